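"""Published evaluation fixtures, reconstructed programmatically.

Two worked datasets accompany the package so the concordance machinery
can be exercised against known results without any download:

* ``csscd_pairs()`` — the 813 CSSCD sickle cell anemia patients with
  both a legacy five-site RFLP diplotype and a phased four-SNP
  diplotype.  Per-class totals and the eight discordant reassignments
  are encoded exactly; individual sample ids are synthetic (the study
  published counts, not per-sample ids).
* ``ipsc_lines()`` — the 55-line sickle-cell iPSC library with its
  original RFLP haplotype and the SNP-based relabeling, transcribed
  line by line.
"""

from __future__ import annotations

from .concordance import PairedLabels

#: CSSCD per-class comparison: reference (RFLP) class -> (total n,
#: discordant test labels).  Concordant samples get test == ref.
_CSSCD_CLASSES: list[tuple[str, int, tuple[str, ...]]] = [
    ("BEN/BEN", 371, ("UNK/BEN", "CAR/CAR", "CAM/BEN", "SEN/BEN")),
    ("BEN/CAR", 226, ("CAR/SEN", "SEN/BEN")),
    ("BEN/SEN", 91, ()),
    ("BEN/CAM", 41, ()),
    ("CAR/CAR", 31, ()),
    ("CAR/SEN", 17, ()),
    ("CAR/CAM", 14, ()),
    ("SEN/CAM", 9, ()),
    ("SEN/SEN", 8, ()),
    ("BEN/AI", 2, ("UNK/SEN", "UNK/SEN")),
    ("CAR/AI", 1, ()),
    ("SEN/AI", 1, ()),
    ("CAM/CAM", 1, ()),
]


def csscd_pairs() -> list[PairedLabels]:
    """The 813-sample CSSCD paired labeling (RFLP reference vs phased
    SNP test)."""
    pairs: list[PairedLabels] = []
    i = 0
    for ref, n, discordant in _CSSCD_CLASSES:
        for test in discordant:
            i += 1
            pairs.append(PairedLabels(f"CSSCD{i:04d}", ref, test))
        for _ in range(n - len(discordant)):
            i += 1
            pairs.append(PairedLabels(f"CSSCD{i:04d}", ref, ref))
    return pairs


#: (line name, RFLP haplotype, SNP-based reclassification)
_IPSC_LINES: list[tuple[str, str, str]] = [
    ("SA108", "AI/AI", "AI/AI"),
    ("SA50-1", "AI/AI", "AI/AI"),
    ("SA106-1", "AI/AI", "AI/AI"),
    ("SA170-1", "AI/AI", "AI/AI"),
    ("SS2-1", "UNK/UNK", "BEN/SEN"),
    ("SS2-1GAG", "UNK/UNK", "BEN/SEN"),
    ("SS12-1", "UNK/UNK", "BEN/CAR"),
    ("SS18-1", "UNK/UNK", "UNK/UNK"),
    ("SS28-1", "UNK/UNK", "BEN/BEN"),
    ("SS36", "UNK/UNK", "BEN/CAR"),
    ("SS41-1", "UNK/UNK", "CAR/CAR"),
    ("SS45-1", "UNK/UNK", "BEN/BEN"),
    ("SS47-1", "UNK/UNK", "BEN/CAR"),
    ("SS48-1", "UNK/UNK", "CAR/CAR"),
    ("SA5-1", "UNK/UNK", "BEN/BEN"),
    ("SA53-1", "UNK/UNK", "BEN/CAR"),
    ("SA208", "UNK/UNK", "UNK/BEN"),
    ("SA138-1", "UNK/UNK", "AI/AI"),
    ("BR-SP-21-1", "UNK/UNK", "BEN/CAR"),
    ("BR-SP-37-1", "UNK/UNK", "CAR/CAM"),
    ("BR-SP-45-1", "UNK/UNK", "CAR/CAR"),
    ("SS24-1", "CAR/CAR", "CAR/CAR"),
    ("SS25-1", "CAR/CAR", "CAR/CAR"),
    ("BR-SP-3-1", "CAR/CAR", "CAR/CAR"),
    ("BR-SP-23-1", "CAR/CAR", "CAR/CAR"),
    ("BR-SP-25-1", "CAR/CAR", "CAR/CAR"),
    ("BR-SP-41-1", "CAR/CAR", "CAR/CAR"),
    ("BR-SP-43-1", "CAR/CAR", "CAR/CAR"),
    ("SS9-1", "BEN/CAR", "BEN/CAR"),
    ("SS13-1", "BEN/CAR", "BEN/CAR"),
    ("SS15-1", "BEN/CAR", "BEN/CAR"),
    ("SS35", "BEN/CAR", "BEN/CAR"),
    ("BR-SP-29-1", "BEN/CAR", "BEN/CAR"),
    ("BR-SP-33-1", "BEN/CAR", "BEN/CAR"),
    ("BR-SP-39-1", "BEN/CAR", "BEN/CAR"),
    ("SS5-1", "BEN/BEN", "BEN/BEN"),
    ("SS14-1", "BEN/BEN", "BEN/BEN"),
    ("SS16-1", "BEN/BEN", "BEN/BEN"),
    ("SS19-1", "BEN/BEN", "BEN/BEN"),
    ("SS29-1", "BEN/BEN", "BEN/BEN"),
    ("SS32", "BEN/BEN", "BEN/BEN"),
    ("SS37", "BEN/BEN", "BEN/BEN"),
    ("SS38", "BEN/BEN", "BEN/BEN"),
    ("SS44-1", "BEN/BEN", "BEN/CAM"),
    ("SS49-1", "BEN/BEN", "CAR/SEN"),
    ("SA36", "BEN/BEN", "BEN/BEN"),
    ("SA40-1", "BEN/BEN", "BEN/BEN"),
    ("SA64", "BEN/BEN", "BEN/BEN"),
    ("SA82-2", "BEN/BEN", "BEN/BEN"),
    ("SA209-1", "BEN/BEN", "BEN/BEN"),
    ("SA210-1", "BEN/BEN", "BEN/BEN"),
    ("BR-SP-31-1", "BEN/BEN", "BEN/BEN"),
    ("SS4-1", "BEN/SEN", "BEN/SEN"),
    ("SS8-2", "SEN/SEN", "SEN/SEN"),
    ("SS43-2", "SEN/SEN", "SEN/SEN"),
]


def ipsc_lines() -> list[PairedLabels]:
    """The 55-line sickle-cell iPSC library relabeling."""
    return [PairedLabels(name, ref, test) for name, ref, test in _IPSC_LINES]
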