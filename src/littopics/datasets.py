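"""Small bundled reference tables for worked examples and checks."""

from __future__ import annotations

import pandas as pd

from .ingest import JournalAggregate

__all__ = ["diatom_journal_aggregates", "diatom_journal_reference_table"]

# The 20 most active journals in the diatom literature, 1991-2018 (SCIE
# extraction): journal, TPD (publications on diatoms), TP (all publications),
# TC (citations of the diatom publications), and the published one-decimal
# ratio columns TPD/TP (%) and TC/TPD used to cross-check the arithmetic.
_JOURNAL_ROWS = [
    ("DIATOM RESEARCH", 483, 602, 3685, 80.2, 7.6),
    ("JOURNAL OF PALEOLIMNOLOGY", 601, 1747, 15380, 34.4, 25.6),
    ("JOURNAL OF PHYCOLOGY", 774, 4524, 31181, 17.1, 40.3),
    ("CRYPTOGAMIE ALGOLOGIE", 116, 706, 756, 16.4, 6.5),
    ("EUROPEAN JOURNAL OF PHYCOLOGY", 268, 1782, 5172, 15.0, 19.3),
    ("JOURNAL OF PLANKTON RESEARCH", 506, 3404, 15694, 14.9, 31.0),
    ("PHYCOLOGICAL RESEARCH", 76, 531, 645, 14.3, 8.5),
    ("AQUATIC MICROBIAL ECOLOGY", 268, 1889, 8505, 14.2, 31.7),
    ("HARMFUL ALGAE", 203, 1497, 4918, 13.6, 24.2),
    ("LIMNOLOGY AND OCEANOGRAPHY", 729, 5635, 45741, 12.9, 62.7),
    ("OCEANOLOGICAL AND HYDROBIOLOGICAL STUDIES", 69, 565, 276, 12.2, 4.0),
    ("DEEP-SEA RESEARCH PART II-TOPICAL STUDIES IN OCEANOGRAPHY", 524, 4460, 23456, 11.7, 44.8),
    ("MARINE MICROPALEONTOLOGY", 150, 1321, 3924, 11.4, 26.2),
    ("FUNDAMENTAL AND APPLIED LIMNOLOGY", 79, 696, 639, 11.4, 8.1),
    ("PROTIST", 91, 910, 3202, 10.0, 35.2),
    ("PHYCOLOGIA", 354, 3709, 6936, 9.5, 19.6),
    ("AQUATIC ECOLOGY", 76, 799, 1121, 9.5, 14.8),
    ("VIE ET MILIEU-LIFE AND ENVIRONMENT", 65, 710, 387, 9.2, 6.0),
    ("BIOFOULING", 131, 1475, 4368, 8.9, 33.3),
    ("MARINE CHEMISTRY", 229, 2770, 10380, 8.3, 45.3),
]


def diatom_journal_aggregates() -> list[JournalAggregate]:
    """The (TPD, TP, TC) input triples for the 20 journals."""
    return [JournalAggregate(j, tpd, tp, tc) for j, tpd, tp, tc, _, _ in _JOURNAL_ROWS]


def diatom_journal_reference_table() -> pd.DataFrame:
    """Inputs plus the published one-decimal ratio columns."""
    return pd.DataFrame(
        _JOURNAL_ROWS,
        columns=["journal", "tpd", "tp", "tc", "tpd_tp_pct", "tc_per_tpd"],
    )
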