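"""Profile (PSSM) construction, windowed scanning and significance.

A desk-scale stand-in for PSI-BLAST/CDD annotation: profiles are built
from seed alignments as per-column amino-acid probability vectors with
Laplace-style pseudocounts, searched against proteomes by ungapped
sliding-window log-odds scoring, and assigned E-values from an empirical
Gumbel null fitted to best-window scores of random background sequences
(mirroring the extreme-value behavior of local alignment scores).
Externally produced hit tables (e.g. from HHpred) can be imported and
merged into gene annotations through the same interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from coconut_census.genome_io import DomainHit, GeneFeature, GenomeRecord, read_table
from coconut_census.templates import AMINO_ACIDS

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_EVALUE_FLOOR = 1e-280

NO_HIT = (float("-inf"), -1)


@dataclass
class GumbelNull:
    """Location/scale of the best-window score null distribution."""

    mu: float
    beta: float

    def pvalue(self, score: float) -> float:
        return float(stats.gumbel_r.sf(score, loc=self.mu, scale=self.beta))


@dataclass
class Profile:
    """Position-specific scoring matrix over the 20 amino acids."""

    name: str
    probs: np.ndarray  # (ncols, 20), rows sum to 1
    background: np.ndarray  # (20,)
    null: GumbelNull | None = None
    # catalytic-column annotation: (1-based column, allowed residues) plus
    # the label to assign when the columns are not satisfied
    catalytic: tuple[tuple[int, str], ...] = ()
    inactive_label: str | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("profile columns must sum to 1")
        self.log_odds = np.log2(self.probs / self.background[None, :])

    @property
    def ncols(self) -> int:
        return int(self.probs.shape[0])

    def consensus(self) -> str:
        return "".join(AMINO_ACIDS[i] for i in np.argmax(self.probs, axis=1))


def encode(seq: str) -> np.ndarray:
    """Residues to integer codes; unknown letters map to index 0 (Ala)."""
    return np.fromiter(
        (AA_INDEX.get(ch, 0) for ch in seq), dtype=np.int64, count=len(seq)
    )


def build_profile(
    msa: list[str],
    pseudocount: float = 1.0,
    name: str = "profile",
    background: np.ndarray | None = None,
    max_gap_fraction: float = 0.5,
) -> Profile:
    """Build a profile from an aligned set of sequences.

    ``p[c][a] = (count + pseudocount * background[a]) / (n_residues + pseudocount)``
    per column, counting non-gap residues only; columns with more than
    ``max_gap_fraction`` gaps are dropped.  Duplicate rows are collapsed
    before counting (minimal sequence weighting), so replicating a
    sequence does not change the profile.
    """
    if not msa:
        raise ValueError("empty alignment")
    width = len(msa[0])
    if any(len(row) != width for row in msa):
        raise ValueError("ragged alignment: unequal row lengths")
    msa = list(dict.fromkeys(msa))  # unique rows, first-seen order
    if background is None:
        background = np.full(20, 0.05)
    columns = []
    n_rows = len(msa)
    for c in range(width):
        residues = [row[c] for row in msa if row[c] not in "-."]
        if len(residues) < n_rows * (1.0 - max_gap_fraction):
            continue
        counts = np.zeros(20)
        for ch in residues:
            idx = AA_INDEX.get(ch.upper())
            if idx is not None:
                counts[idx] += 1
        n_eff = counts.sum()
        columns.append((counts + pseudocount * background) / (n_eff + pseudocount))
    if not columns:
        raise ValueError("no usable columns after gap filtering")
    return Profile(name=name, probs=np.array(columns), background=background)


def scan_protein(profile: Profile, seq: str) -> tuple[float, int]:
    """Best ungapped window: (bit score, 1-based start); ties -> smallest start.

    Returns the ``NO_HIT`` sentinel when the sequence is shorter than the
    profile.
    """
    n = profile.ncols
    if len(seq) < n:
        return NO_HIT
    codes = encode(seq)
    windows = np.lib.stride_tricks.sliding_window_view(codes, n)
    scores = profile.log_odds[np.arange(n)[None, :], windows].sum(axis=1)
    best = int(np.argmax(scores))  # argmax takes the first maximum
    return float(scores[best]), best + 1


def scan_protein_all(
    profile: Profile, seq: str, max_hits: int = 4
) -> list[tuple[float, int]]:
    """Up to ``max_hits`` non-overlapping windows by descending score.

    Greedy: take the best window, mask overlapping starts, repeat — so
    tandem copies of a domain each get a hit.
    """
    n = profile.ncols
    if len(seq) < n:
        return []
    codes = encode(seq)
    windows = np.lib.stride_tricks.sliding_window_view(codes, n)
    scores = profile.log_odds[np.arange(n)[None, :], windows].sum(axis=1).copy()
    out: list[tuple[float, int]] = []
    for _ in range(max_hits):
        best = int(np.argmax(scores))
        if not np.isfinite(scores[best]):
            break
        out.append((float(scores[best]), best + 1))
        lo = max(0, best - n + 1)
        scores[lo : best + n] = -np.inf
        if not np.isfinite(scores).any():
            break
    return out


def calibrate(
    profile: Profile,
    n_shuffles: int = 200,
    target_len: int = 300,
    seed: int = 0,
) -> GumbelNull:
    """Fit a Gumbel null to best-window scores of random background sequences."""
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be >= 100")
    rng = np.random.default_rng(seed)
    best_scores = np.empty(n_shuffles)
    n = profile.ncols
    for i in range(n_shuffles):
        codes = rng.choice(20, size=target_len, p=profile.background / profile.background.sum())
        windows = np.lib.stride_tricks.sliding_window_view(codes, n)
        scores = profile.log_odds[np.arange(n)[None, :], windows].sum(axis=1)
        best_scores[i] = scores.max()
    if np.std(best_scores) < 1e-9:
        raise ValueError("degenerate null: all shuffle scores equal")
    mu, beta = stats.gumbel_r.fit(best_scores)
    null = GumbelNull(mu=float(mu), beta=float(beta))
    profile.null = null
    return null


def evalue(profile: Profile, score: float, database_size: int) -> float:
    if profile.null is None:
        raise ValueError(f"profile {profile.name} is not calibrated")
    return max(database_size * profile.null.pvalue(score), _EVALUE_FLOOR)


@dataclass
class SearchHit:
    profile_name: str
    gene_id: str
    score: float
    start_aa: int
    end_aa: int
    evalue: float


def _iter_genes(genomes: list[GenomeRecord]):
    for genome in genomes:
        for gene in genome.genes:
            yield gene


def search_proteome(
    profiles: list[Profile],
    genomes: list[GenomeRecord],
    evalue_max: float = 10.0,
    attach: bool = True,
    refine_catalytic: bool = True,
) -> list[SearchHit]:
    """Scan every protein with every profile; keep hits with E <= evalue_max.

    Hits are attached to ``GeneFeature.annotations`` as DomainHits.  For
    profiles carrying catalytic-column annotation, hits whose catalytic
    residues are absent are relabeled (active PD-DxK vs inactivated
    iPD-DxK).
    """
    for p in profiles:
        if p.null is None:
            raise ValueError(f"profile {p.name} is not calibrated")
    genes = [g for g in _iter_genes(genomes) if g.protein_seq]
    db_size = len(genes)
    hits: list[SearchHit] = []
    for profile in profiles:
        for gene in genes:
            for score, start in scan_protein_all(profile, gene.protein_seq):
                ev = evalue(profile, score, db_size)
                if ev > evalue_max:
                    break  # descending scores: the rest fail too
                end = start + profile.ncols - 1
                label = profile.name
                if refine_catalytic and profile.catalytic and profile.inactive_label:
                    window = gene.protein_seq[start - 1 : end]
                    ok = all(
                        col <= len(window) and window[col - 1] in allowed
                        for col, allowed in profile.catalytic
                    )
                    if not ok:
                        label = profile.inactive_label
                hits.append(
                    SearchHit(
                        profile_name=label, gene_id=gene.gene_id, score=score,
                        start_aa=start, end_aa=min(end, gene.protein_length),
                        evalue=ev,
                    )
                )
                if attach:
                    gene.annotations.append(
                        DomainHit(
                            domain_label=label, start_aa=start,
                            end_aa=min(end, gene.protein_length),
                            evalue=ev, source="builtin",
                        )
                    )
    return hits


def builtin_profiles(
    labels: tuple[str, ...] | list[str],
    pseudocount: float = 1.0,
) -> list[Profile]:
    """Profiles built from the bundled seed alignments for the given labels.

    The PD-DxK profile carries its catalytic-column annotation so hits can
    be relabeled iPD-DxK when the catalytic residues are substituted.
    """
    from coconut_census.templates import TEMPLATES, seed_alignment

    out = []
    for label in labels:
        profile = build_profile(seed_alignment(label), pseudocount, name=label)
        tmpl = TEMPLATES[label]
        if tmpl.catalytic:
            profile.catalytic = tmpl.catalytic
            profile.inactive_label = "iPD-DxK" if label == "PD-DxK" else None
        out.append(profile)
    return out


def calibrate_all(
    profiles: list[Profile],
    n_shuffles: int = 200,
    target_len: int = 300,
    seed: int = 0,
) -> None:
    """Calibrate every profile with a seed derived from its name order."""
    for i, profile in enumerate(profiles):
        calibrate(profile, n_shuffles=n_shuffles, target_len=target_len,
                  seed=seed + i)


def import_external_hits(
    tsv_path: str | Path, genomes: list[GenomeRecord]
) -> list[SearchHit]:
    """Merge an external hit table (gene_id, domain_label, start, end, evalue).

    Rows with unknown gene ids or negative E-values are skipped with a
    warning; duplicate (gene, domain) rows keep the best E-value.
    """
    genes = {g.gene_id: g for g in _iter_genes(genomes)}
    best: dict[tuple[str, str], SearchHit] = {}
    for row in read_table(tsv_path):
        gene = genes.get(row["gene_id"])
        if gene is None:
            warnings.warn(f"external hit for unknown gene {row['gene_id']!r} skipped",
                          stacklevel=2)
            continue
        ev = float(row["evalue"])
        if ev < 0:
            warnings.warn(f"negative evalue for {row['gene_id']} rejected", stacklevel=2)
            continue
        hit = SearchHit(
            profile_name=row["domain_label"], gene_id=row["gene_id"],
            score=float(row.get("score", 0.0) or 0.0),
            start_aa=int(row["start"]), end_aa=int(row["end"]), evalue=ev,
        )
        key = (hit.gene_id, hit.profile_name)
        if key not in best or hit.evalue < best[key].evalue:
            best[key] = hit
    merged = sorted(best.values(), key=lambda h: (h.gene_id, h.profile_name))
    for hit in merged:
        genes[hit.gene_id].annotations.append(
            DomainHit(
                domain_label=hit.profile_name, start_aa=hit.start_aa,
                end_aa=hit.end_aa, evalue=hit.evalue, source="external",
            )
        )
    return merged
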