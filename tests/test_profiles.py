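"""Profile construction, window scanning and empirical significance."""

import numpy as np
import pytest

from coconut_census import profiles as pf
from coconut_census.genome_io import write_report
from coconut_census.synthetic import generate_cohort
from coconut_census.templates import AMINO_ACIDS, DISCOVERY_LABELS, TEMPLATES


def brute_force_best_window(profile, seq):
    """Independent oracle: enumerate every window explicitly."""
    n = profile.ncols
    best = (float("-inf"), -1)
    for start in range(len(seq) - n + 1):
        score = sum(
            profile.log_odds[c, pf.AA_INDEX.get(seq[start + c], 0)]
            for c in range(n)
        )
        if score > best[0]:
            best = (score, start + 1)
    return best


class TestBuildProfile:
    def test_single_sequence_zero_pseudocount_limit(self):
        profile = pf.build_profile(["ACD"], pseudocount=1e-9)
        for col, aa in enumerate("ACD"):
            assert profile.probs[col, pf.AA_INDEX[aa]] == pytest.approx(1.0)

    def test_duplication_invariance(self):
        p1 = pf.build_profile(["ACDEF"], pseudocount=1.0)
        p2 = pf.build_profile(["ACDEF", "ACDEF"], pseudocount=1.0)
        assert np.allclose(p1.probs, p2.probs)

    def test_hand_arithmetic_column(self):
        # first column {A,A,C,C}, uniform background, pseudocount 1:
        # p(A) = (2 + 0.05) / (4 + 1) = 0.41  (rows distinct overall)
        profile = pf.build_profile(["AW", "AY", "CF", "CM"], pseudocount=1.0)
        assert profile.probs[0, pf.AA_INDEX["A"]] == pytest.approx(0.41)
        assert profile.probs[0, pf.AA_INDEX["C"]] == pytest.approx(0.41)

    def test_ragged_alignment_errors(self):
        with pytest.raises(ValueError, match="ragged"):
            pf.build_profile(["AC", "ACD"])

    def test_empty_alignment_errors(self):
        with pytest.raises(ValueError):
            pf.build_profile([])

    def test_majority_gap_columns_dropped(self):
        profile = pf.build_profile(["A-C", "G-C", "ADC"])
        assert profile.ncols == 2

    def test_columns_sum_to_one_and_log_odds_definition(self):
        profile = pf.build_profile(["ACD", "AVD"], pseudocount=0.7)
        assert np.allclose(profile.probs.sum(axis=1), 1.0)
        assert np.allclose(
            profile.log_odds,
            np.log2(profile.probs / profile.background[None, :]),
        )


class TestScanProtein:
    def test_consensus_scores_sum_of_max(self):
        profile = pf.build_profile(["ACDEF", "ACDEF", "ACDFF"])
        consensus = profile.consensus()
        score, start = pf.scan_protein(profile, consensus)
        assert start == 1
        assert score == pytest.approx(profile.log_odds.max(axis=1).sum())

    def test_sequence_equal_to_ncols_single_window(self):
        profile = pf.build_profile(["ACDEF"])
        score, start = pf.scan_protein(profile, "MKLVW")
        assert start == 1

    def test_too_short_returns_sentinel(self):
        profile = pf.build_profile(["ACDEF"])
        assert pf.scan_protein(profile, "ACD") == pf.NO_HIT

    def test_matches_brute_force_oracle(self, rng):
        for trial in range(20):
            cols = int(rng.integers(5, 31))
            msa = ["".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, cols))
                   for _ in range(3)]
            profile = pf.build_profile(msa)
            seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 200))
            assert pf.scan_protein(profile, seq) == \
                pytest.approx(brute_force_best_window(profile, seq))


class TestCalibration:
    def test_deterministic_under_seed(self):
        profile = pf.build_profile(["ACDEFGHIKL"] * 3)
        n1 = pf.calibrate(profile, n_shuffles=150, seed=3)
        n2 = pf.calibrate(profile, n_shuffles=150, seed=3)
        assert (n1.mu, n1.beta) == (n2.mu, n2.beta)

    def test_requires_min_shuffles(self):
        profile = pf.build_profile(["ACDEFGHIKL"])
        with pytest.raises(ValueError):
            pf.calibrate(profile, n_shuffles=10)

    def test_degenerate_null_errors(self):
        # uniform profile scores every sequence identically
        uniform = pf.Profile("u", np.full((5, 20), 0.05), np.full(20, 0.05))
        with pytest.raises(ValueError, match="degenerate"):
            pf.calibrate(uniform, n_shuffles=100)

    def test_planted_template_above_null_percentile(self):
        label = "GTPase"
        profile = pf.build_profile(
            [TEMPLATES[label].core], name=label
        )
        pf.calibrate(profile, n_shuffles=300, seed=1)
        score, _ = pf.scan_protein(profile, TEMPLATES[label].core)
        rng = np.random.default_rng(2)
        null_scores = []
        for _ in range(300):
            seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, 300))
            null_scores.append(pf.scan_protein(profile, seq)[0])
        assert score > np.quantile(null_scores, 0.99)


@pytest.fixture(scope="module")
def searched():
    genomes, truths = generate_cohort(1, seed=13)
    discovery = pf.builtin_profiles(DISCOVERY_LABELS)
    pf.calibrate_all(discovery, seed=0)
    hits = pf.search_proteome(discovery, genomes, evalue_max=10.0,
                              attach=False)
    return genomes, truths, discovery, hits


class TestSearchProteome:

    def test_planted_gtpase_genes_all_hit(self, searched):
        genomes, truths, _, hits = searched
        hit_genes = {h.gene_id for h in hits if h.profile_name == "GTPase"}
        for truth in truths:
            if truth.b_gene_id and truth.filter_design == "primary":
                design = truth.gene_designs[truth.b_gene_id]
                if any(d[0] == "GTPase" for d in design.domains):
                    assert truth.b_gene_id in hit_genes

    def test_evalue_zero_gives_empty(self, searched):
        genomes, _, discovery, _ = searched
        assert pf.search_proteome(discovery, genomes, evalue_max=0.0,
                                  attach=False) == []

    def test_monotone_in_evalue_threshold(self, searched):
        genomes, _, discovery, _ = searched
        loose = pf.search_proteome(discovery, genomes, evalue_max=10.0,
                                   attach=False)
        strict = pf.search_proteome(discovery, genomes, evalue_max=0.001,
                                    attach=False)
        loose_keys = {(h.profile_name, h.gene_id, h.start_aa) for h in loose}
        strict_keys = {(h.profile_name, h.gene_id, h.start_aa) for h in strict}
        assert strict_keys <= loose_keys

    def test_deterministic(self, searched):
        genomes, _, discovery, hits = searched
        again = pf.search_proteome(discovery, genomes, evalue_max=10.0,
                                   attach=False)
        assert [(h.gene_id, h.profile_name, h.start_aa, h.score) for h in hits] == \
            [(h.gene_id, h.profile_name, h.start_aa, h.score) for h in again]

    def test_uncalibrated_profile_errors(self):
        genomes, _ = generate_cohort(1, seed=1)
        raw = pf.builtin_profiles(("CSD",))
        with pytest.raises(ValueError, match="not calibrated"):
            pf.search_proteome(raw, genomes)


class TestExternalHits:
    def _write(self, path, rows):
        write_report(rows, path,
                     columns=["gene_id", "domain_label", "start", "end", "evalue"])

    def test_import_merge_and_dedup(self, tmp_path):
        genomes, _ = generate_cohort(1, seed=2)
        gid = genomes[0].genes[0].gene_id
        table = tmp_path / "ext.tsv"
        self._write(table, [
            {"gene_id": gid, "domain_label": "EVE", "start": 1, "end": 30,
             "evalue": 1e-5},
            {"gene_id": gid, "domain_label": "EVE", "start": 2, "end": 31,
             "evalue": 1e-8},  # duplicate: keep the better one
            {"gene_id": gid, "domain_label": "YTH", "start": 5, "end": 40,
             "evalue": 1e-4},
        ])
        merged = pf.import_external_hits(table, genomes)
        assert len(merged) == 2
        eve = next(h for h in merged if h.profile_name == "EVE")
        assert eve.evalue == pytest.approx(1e-8)
        assert all(h.source == "external"
                   for h in genomes[0].genes[0].annotations)

    def test_unknown_gene_and_negative_evalue_skipped(self, tmp_path):
        genomes, _ = generate_cohort(1, seed=2)
        gid = genomes[0].genes[0].gene_id
        table = tmp_path / "ext.tsv"
        self._write(table, [
            {"gene_id": "nope", "domain_label": "EVE", "start": 1, "end": 30,
             "evalue": 1e-5},
            {"gene_id": gid, "domain_label": "EVE", "start": 1, "end": 30,
             "evalue": -1.0},
        ])
        with pytest.warns(UserWarning):
            merged = pf.import_external_hits(table, genomes)
        assert merged == []
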