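"""Fixed domain sequence templates and built-in seed alignments.

Each domain label has a deterministic "core" template — the conserved
segment that seed alignments and the built-in profile scanner target —
plus, for a few labels, literal sequence motifs at fixed offsets (Walker
A/B and the Nx(xx)D signature in the McrB-like GTPase, RxxxxH/RxH in
HEPN, the PD-(D/E)xK catalytic triad, CPxC zinc-binding repeats).

Unconstrained template and linker positions are drawn from a reduced
15-letter alphabet that omits K, N, R, C and H.  Those residues appear
only where a motif plants them, so motif truth is unambiguous by
construction: no spurious Walker A (needs K), signature N-x(1,3)-D
(needs N), HEPN R-x-H / R-x(4)-H (need R and H) or CPxC (needs C) can
arise in or adjacent to a background segment.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
# 20 letters minus K, N, R, C, H (see module docstring; H is reserved so a
# planted RxH cannot be extended into a spurious R-x(4)-H by a background
# histidine).
SAFE_ALPHABET = "ADEFGILMPQSTVWY"
# GTPase Walker A -> Walker B spacer additionally omits D/E so that no
# hydrophobic-run + acidic-pair Walker B pattern precedes the planted one.
SPACER_ALPHABET = "AFGILMPQSTVWY"

WALKER_A = "GPSGSGKS"
WALKER_B = "ILVIDE"
SIGNATURES = {"NxD": "NVDE", "NxxD": "NVVDE", "NxxxD": "NVVVDE"}
HEPN_MOTIFS = {"RxxxxH": "RADDAH", "RxH": "RSH"}
PDDXK_ACTIVE = "PDGLDIK"
PDDXK_INACTIVE = "PAGLSIV"
HEPTAD = "IAALEQK"  # a=I, d=L hydrophobic; e/g charged
CPXC_UNITS = ("CPAC", "CPLC", "CPGC")


def _label_rng(label: str, salt: str = "tmpl") -> np.random.Generator:
    digest = hashlib.sha256(f"{salt}:{label}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "big"))


def _rand(rng: np.random.Generator, n: int, alphabet: str = SAFE_ALPHABET) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), n))


@dataclass(frozen=True)
class DomainTemplate:
    """A domain's profile-detectable core plus motif bookkeeping."""

    label: str
    core: str
    # (motif_name, 1-based start offset within core) for motifs inside core
    core_motifs: tuple[tuple[str, int], ...] = ()
    # catalytic columns for active/inactive discrimination: (offset, allowed)
    catalytic: tuple[tuple[int, str], ...] = ()


def _gtpase_core(rng: np.random.Generator, pre: int, spacer: int) -> tuple[str, int, int]:
    """Core = pre + Walker A + spacer + Walker B; returns (core, posA, posB)."""
    core = _rand(rng, pre) + WALKER_A + _rand(rng, spacer, SPACER_ALPHABET) + WALKER_B
    return core, pre + 1, pre + len(WALKER_A) + spacer + 1


def _build_templates() -> dict[str, DomainTemplate]:
    templates: dict[str, DomainTemplate] = {}

    rng = _label_rng("GTPase")
    core, pos_a, pos_b = _gtpase_core(rng, pre=12, spacer=20)
    templates["GTPase"] = DomainTemplate(
        "GTPase", core,
        core_motifs=(("WalkerA", pos_a), ("WalkerB", pos_b)),
    )

    # Divergent GTPase layout: same literals, different flanking geometry, so
    # it is found by its own discovery profile but not by the canonical
    # GTPase annotation profile (ungapped scanning cannot bridge the shift).
    rng = _label_rng("GTPase_cryptic")
    core, pos_a, pos_b = _gtpase_core(rng, pre=9, spacer=14)
    templates["GTPase_cryptic"] = DomainTemplate(
        "GTPase_cryptic", core,
        core_motifs=(("WalkerA", pos_a), ("WalkerB", pos_b)),
    )

    rng = _label_rng("HEPN")
    lead = _rand(rng, 34)
    templates["HEPN"] = DomainTemplate(
        "HEPN", lead + HEPN_MOTIFS["RxxxxH"],
        core_motifs=(("RxxxxH", len(lead) + 1),),
    )

    rng = _label_rng("PD-DxK")
    left, right = _rand(rng, 18), _rand(rng, 15)
    cat_start = len(left) + 1
    templates["PD-DxK"] = DomainTemplate(
        "PD-DxK", left + PDDXK_ACTIVE + right,
        core_motifs=(("PD-DxK", cat_start),),
        catalytic=(
            (cat_start + 1, "DE"),   # D of "PD"
            (cat_start + 4, "DE"),   # D/E of D-x-K
            (cat_start + 6, "K"),    # K of D-x-K
        ),
    )

    plain_lengths = {
        "DUF2357": 48, "DUF3578": 42, "CSD": 38, "YTH": 42, "IG": 40,
        "ZnR": 22, "PYD": 36, "REC": 40, "SPB": 38, "RTL": 36,
        "OB-stalk": 40, "wHTH": 38, "Sul7s-wHTH": 40, "PLD": 42, "Vsr": 40,
        "Hsp70-NBD/SBD": 50, "HEAT": 40, "HTH": 34, "VWA": 42, "PP2C": 44,
        "STK": 44, "SF1-helicase": 52, "CARF": 44, "RtcR-ATPase": 46,
        "HsdR": 50, "HsdM": 48, "HsdS": 44, "ShdA": 48, "Druantia": 46,
        "Mod": 42, "Res": 44,
        # McrB/McrC alias families used for decoys and filter tests
        "MoxR": 40, "AAA_5": 42, "COG4127": 38, "DUF4357": 40, "Smc": 44,
        "WEMBL": 38, "Myosin_tail_1": 42, "EVE": 40, "Mrr_N": 38,
        "pfam01878": 40, "McrBC": 42, "McrC": 40, "PF09823": 38,
        "COG1700": 42, "PDDEXK_7": 40, "RE_LlaJI": 38,
    }
    for label, length in plain_lengths.items():
        templates[label] = DomainTemplate(label, _rand(_label_rng(label), length))

    return templates


TEMPLATES: dict[str, DomainTemplate] = _build_templates()

# Labels whose profiles seed the discovery search (permissive E <= 10 pass);
# all remaining templates back the domain-annotation search (E = 0.001).
DISCOVERY_LABELS = ("GTPase", "GTPase_cryptic", "DUF2357")
# Role each discovery profile testifies to, for the rescue filters.
DISCOVERY_ROLE = {"GTPase": "B", "GTPase_cryptic": "B", "DUF2357": "C"}

ANNOTATION_LABELS = tuple(
    sorted(label for label in TEMPLATES if label != "GTPase_cryptic")
)


def seed_alignment(
    label: str, n_seqs: int = 8, divergence: float = 0.10
) -> list[str]:
    """Deterministic ungapped seed MSA: mutated copies of the label's core.

    Substitutions are drawn from the full 20-letter alphabet, emulating a
    family alignment around the conserved core.
    """
    core = TEMPLATES[label].core
    rng = _label_rng(label, salt="msa")
    rows = []
    for _ in range(n_seqs):
        chars = list(core)
        for i in range(len(chars)):
            if rng.random() < divergence:
                chars[i] = AMINO_ACIDS[rng.integers(0, 20)]
        rows.append("".join(chars))
    return rows


def gtpase_variant(label: str, variant: str) -> tuple[str, int, int, str, str]:
    """Signature-class flavor of a GTPase core.

    Each signature class (NxD / NxxD / NxxxD) carries a fixed set of
    substitutions (~15% of non-motif positions) relative to the base core,
    mimicking clade-level divergence: the annotation profile still finds
    every flavor, while trees separate the classes.  Returns
    (core, Walker A offset, Walker B offset, post-Walker-B spacer,
    conserved post-signature tail).
    """
    base = TEMPLATES[label]
    offsets = dict(base.core_motifs)
    pos_a, pos_b = offsets["WalkerA"], offsets["WalkerB"]
    literal = set(range(pos_a - 1, pos_a - 1 + len(WALKER_A)))
    literal |= set(range(pos_b - 1, pos_b - 1 + len(WALKER_B)))
    spacer = range(pos_a - 1 + len(WALKER_A), pos_b - 1)
    rng = _label_rng(f"{label}:{variant}", salt="var")
    chars = list(base.core)
    for i in range(len(chars)):
        if i in literal:
            continue
        if rng.random() < 0.15:
            alphabet = SPACER_ALPHABET if i in spacer else SAFE_ALPHABET
            chars[i] = alphabet[rng.integers(0, len(alphabet))]
    post_spacer = _rand(rng, 6)
    tail = _rand(rng, 30)  # conserved extent of the domain past the signature
    return "".join(chars), pos_a, pos_b, post_spacer, tail


def reference_gtpase_sequence(signature: str = "NxD") -> str:
    """Canonical full GTPase domain: core + spacer + signature + tail.

    Used as the insert-free reference when testing members for the helical
    insert between Walker B and the signature motif.
    """
    rng = _label_rng("GTPase_ref")
    sig = SIGNATURES[signature]
    return TEMPLATES["GTPase"].core + _rand(rng, 6) + sig + _rand(rng, 8)
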