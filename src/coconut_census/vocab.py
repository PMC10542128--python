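"""Controlled vocabularies: domain labels, alias sets, subtype names.

The alias whitelists are the McrB- and McrC-side domain label sets used by
the neighborhood filter: a locus is accepted outright when it carries an
McrB GTPase hit, or hits to at least one alias from each side.
"""

from __future__ import annotations

from dataclasses import dataclass

# Domain labels used for architecture typing (ordered-domain strings).
ARCHITECTURE_VOCAB = frozenset(
    {
        "GTPase", "DUF2357", "DUF3578", "EVE", "YTH", "CSD", "IG", "ZnR",
        "PD-DxK", "iPD-DxK", "CC", "PYD", "REC", "SPB", "RTL", "OB-stalk",
        "wHTH", "Sul7s-wHTH", "HEPN", "PLD", "Vsr", "Hsp70-NBD/SBD", "HEAT",
        "HTH", "VWA", "PP2C", "STK", "SF1-helicase", "CARF", "RtcR-ATPase",
        "HsdR", "HsdM", "HsdS", "ShdA", "Druantia", "Mod", "Res", "other",
    }
)

# Labels equivalent to a direct McrB GTPase domain hit (clause 1 of the
# primary filter).
GTPASE_LABELS = frozenset({"GTPase", "COG1401"})

MCRB_ALIASES = frozenset(
    {
        "MoxR", "AAA_5", "COG4127", "DUF4357", "Smc", "WEMBL",
        "Myosin_tail_1", "DUF3578", "EVE", "Mrr_N", "pfam01878", "COG1401",
    }
)

MCRC_ALIASES = frozenset(
    {"McrBC", "McrC", "PF09823", "DUF2357", "COG1700", "PDDEXK_7", "RE_LlaJI"}
)

SUBTYPES = (
    "mcrbc-classic", "I-A", "I-B", "pseudo-I-B", "I-C",
    "II", "III-A", "III-B", "III-C",
)

PLANT_SUBTYPES = SUBTYPES + ("decoy",)

SUBTYPE_CALLS = (
    "I-A", "I-B", "pseudo-I-B", "I-C", "II", "III-A", "III-B", "III-C",
    "coconut-unclassified", "non-coconut",
)

# Expected pipeline call for each planted subtype (classic McrBC carries the
# ancestral NxxD signature, hence is a valid system but not a CoCoNuT).
EXPECTED_CALL = {s: s for s in SUBTYPES} | {"mcrbc-classic": "non-coconut"}


@dataclass(frozen=True)
class AliasVocabulary:
    """Alias label sets for the neighborhood filters."""

    mcrb_aliases: frozenset[str] = MCRB_ALIASES
    mcrc_aliases: frozenset[str] = MCRC_ALIASES
    gtpase_labels: frozenset[str] = GTPASE_LABELS

    def is_gtpase(self, label: str) -> bool:
        return label in self.gtpase_labels

    def is_mcrb_alias(self, label: str) -> bool:
        return label in self.mcrb_aliases or label in self.gtpase_labels

    def is_mcrc_alias(self, label: str) -> bool:
        return label in self.mcrc_aliases

    def is_alias(self, label: str) -> bool:
        return self.is_mcrb_alias(label) or self.is_mcrc_alias(label)


DEFAULT_VOCAB = AliasVocabulary()
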