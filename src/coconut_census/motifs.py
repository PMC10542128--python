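"""Sequence-motif detection: Walker A/B, Nx(xx)D signature, HEPN, CPxC.

All positions are 1-based indices of the first motif residue.  The
Nx(xx)D signature family partitions McrB-like GTPases: the ancestral
NxxD, the single-residue-deletion NxD that defines the CoCoNuT branch,
and the expanded NxxxD.  Since the shorter spacing is the derived,
defining state, a sequence presenting several candidate signatures is
called by the fewest intervening residues first (nearest to Walker B
among equals).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

WALKER_A_RE = re.compile(r"[AG].{4}GK[ST]")
# hydrophobic x4 followed by two acidics; deliberately loose
WALKER_B_RE = re.compile(r"[ILVMFA]{4}[DE][DE]")
SIGNATURE_RE = re.compile(r"(?=(N.{1,3}D))")
HEPN_LONG_RE = re.compile(r"(?=(R.{4}H))")
HEPN_SHORT_RE = re.compile(r"(?=(R.H))")
CPXC_RE = re.compile(r"CP.C")

WALKER_B_LEN = 6
SIGNATURE_WINDOW = 120  # aa downstream of Walker B searched for the signature


@dataclass
class MotifCall:
    gene_id: str
    motif_class: str  # NxD | NxxD | NxxxD | none
    n_pos: int | None = None
    d_pos: int | None = None
    following_residue: str | None = None
    walker_a_pos: int | None = None
    walker_b_pos: int | None = None
    ambiguous: bool = False  # several candidate signatures in the window


@dataclass
class HepnCall:
    gene_id: str
    motif: str  # RxxxxH | RxH
    position: int


def find_walker_motifs(seq: str) -> tuple[int | None, int | None]:
    """Leftmost Walker A, then leftmost Walker B downstream of it.

    Returns 1-based start positions, or None sentinels when absent.
    """
    m_a = WALKER_A_RE.search(seq)
    if m_a is None:
        return None, None
    m_b = WALKER_B_RE.search(seq, m_a.end())
    if m_b is None:
        return m_a.start() + 1, None
    return m_a.start() + 1, m_b.start() + 1


def classify_signature_motif(
    seq: str,
    walker_b_pos: int,
    gene_id: str = "",
    window: int = SIGNATURE_WINDOW,
    walker_a_pos: int | None = None,
) -> MotifCall:
    """Classify the Nx(xx)D signature downstream of Walker B.

    Searches ``window`` residues past the end of the Walker B motif; the
    candidate with the fewest intervening residues wins, and among equal
    spacings the one nearest Walker B.
    """
    call = MotifCall(gene_id=gene_id, motif_class="none",
                     walker_a_pos=walker_a_pos, walker_b_pos=walker_b_pos)
    search_start = walker_b_pos - 1 + WALKER_B_LEN  # 0-based
    region = seq[search_start : search_start + window]
    # enumerate every (N position, spacing) pair: a single N can head
    # several candidate signatures (e.g. NVDE followed by another D)
    candidates: list[tuple[int, int]] = []  # (spacing, 0-based N pos in region)
    for i, ch in enumerate(region):
        if ch != "N":
            continue
        for spacing in (1, 2, 3):
            d = i + spacing + 1
            if d < len(region) and region[d] == "D":
                candidates.append((spacing, i))
    if not candidates:
        return call
    spacing, rel = min(candidates, key=lambda t: (t[0], t[1]))
    call.ambiguous = len(candidates) > 1
    call.motif_class = {1: "NxD", 2: "NxxD", 3: "NxxxD"}[spacing]
    call.n_pos = search_start + rel + 1
    call.d_pos = call.n_pos + spacing + 1
    call.following_residue = seq[call.d_pos] if call.d_pos < len(seq) else None
    return call


def scan_gtpase_motifs(seq: str, gene_id: str = "",
                       window: int = SIGNATURE_WINDOW) -> MotifCall:
    """Walker A/B then signature classification in one pass."""
    walker_a, walker_b = find_walker_motifs(seq)
    if walker_b is None:
        return MotifCall(gene_id=gene_id, motif_class="none",
                         walker_a_pos=walker_a)
    return classify_signature_motif(seq, walker_b, gene_id=gene_id,
                                    window=window, walker_a_pos=walker_a)


def find_hepn_motifs(
    seq: str, span: tuple[int, int] | None = None, gene_id: str = ""
) -> list[HepnCall]:
    """All RxxxxH / RxH matches inside the (1-based, inclusive) span.

    An RxH nested inside an RxxxxH match is reported once, as RxxxxH.
    Calls come back in N-to-C order.
    """
    if span is None:
        span = (1, len(seq))
    lo, hi = span[0] - 1, span[1]
    region = seq[lo:hi]
    calls: list[HepnCall] = []
    long_spans: list[tuple[int, int]] = []
    for m in HEPN_LONG_RE.finditer(region):
        start = m.start()
        long_spans.append((start, start + 6))
        calls.append(HepnCall(gene_id=gene_id, motif="RxxxxH", position=lo + start + 1))
    for m in HEPN_SHORT_RE.finditer(region):
        start, end = m.start(), m.start() + 3
        if any(s <= start and end <= e for s, e in long_spans):
            continue
        calls.append(HepnCall(gene_id=gene_id, motif="RxH", position=lo + start + 1))
    calls.sort(key=lambda c: c.position)
    return calls


def count_cpxc(seq: str) -> int:
    """Number of non-overlapping C-P-x-C zinc-binding motifs."""
    return len(CPXC_RE.findall(seq))


# ---------------------------------------------------------------------------
# Helical-insert detection on alignments


def _seq_pos_to_column(gapped: str, pos: int) -> int:
    """1-based ungapped position -> 0-based alignment column."""
    count = 0
    for col, ch in enumerate(gapped):
        if ch not in "-.":
            count += 1
            if count == pos:
                return col
    raise ValueError(f"position {pos} beyond sequence of row")


def detect_helical_insert(
    msa: list[tuple[str, str]],
    member_id: str,
    insert_min: int = 30,
    window: int = SIGNATURE_WINDOW,
) -> bool:
    """True iff the member carries >= insert_min unaligned residues between
    its Walker B and signature motifs, relative to the cluster consensus.

    ``msa`` is a list of (row id, gapped sequence).  A column counts as
    unaligned for the member when the member has a residue there but more
    than half of the remaining rows (the cluster consensus) have a gap.
    """
    rows = dict(msa)
    if member_id not in rows:
        raise ValueError(f"member {member_id!r} not in alignment")
    gapped = rows[member_id]
    ungapped = gapped.replace("-", "").replace(".", "")
    call = scan_gtpase_motifs(ungapped, window=window)
    if call.walker_b_pos is None or call.n_pos is None:
        raise ValueError("Walker B / signature motif not found in member")
    col_b_end = _seq_pos_to_column(gapped, call.walker_b_pos + WALKER_B_LEN - 1)
    col_n = _seq_pos_to_column(gapped, call.n_pos)
    others = [row for rid, row in msa if rid != member_id]
    inserted = 0
    for col in range(col_b_end + 1, col_n):
        if gapped[col] in "-.":
            continue
        gaps = sum(1 for row in others if row[col] in "-.")
        if others and gaps * 2 > len(others):
            inserted += 1
    return inserted >= insert_min
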