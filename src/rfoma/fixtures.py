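"""Synthetic stand-in for the published *Rf1* locus organization.

The real copy sequences (DDBJ AB646133/AB646135) are not bundled; these
generated transcripts reproduce the polymorphism *structure* the analysis
relies on — a 6-bp exon-1 indel splitting the NK-198 copies 1/4 vs 2/3, two
3' trailer SNPs splitting 4 | 3 | 1+2, a 3-bp exon-1 indel separating
200-kDa generative from non-generative copies, and allele-private SNPs so
every cluster member is distinguishable.  Real sequences can be dropped in
through :func:`rfoma.catalog.load_catalog` with the same metadata schema.
"""

from __future__ import annotations

from dataclasses import replace

from .catalog import ParalogCopy, RfAllele
from .simulate import PlannedVariant, make_paralog_family

BASE_LENGTH = 1100
FEATURES = (("exon", 0, 400), ("exon", 400, 900), ("utr3", 900, 1100))

# copy order (0-based index) in the generated family
COPY_IDS = (
    "orf20_NK-198-1",
    "orf20_NK-198-2",
    "orf20_NK-198-3",
    "orf20_NK-198-4",
    "orf20_NK-305-1",
    "orf20_NK-305-2",
    "orf20_NK-219-1",
    "orf20_NK-219-2",
    "orf20_NK-219-3",
    "orf20_TK-81",
    "orf20_PI-615522",
    "orf20_Fukkoku",
)

GENERATIVE = frozenset(
    {
        "orf20_NK-198-1",
        "orf20_NK-198-2",
        "orf20_NK-198-3",
        "orf20_NK-198-4",
        "orf20_NK-305-1",
        "orf20_Fukkoku",
    }
)
PSEUDOGENES = frozenset({"orf20_NK-219-1"})

_ALLELES = (
    ("NK-198_Rf1", "dominant", COPY_IDS[0:4]),
    ("NK-305_Rf1", "semi_dominant", COPY_IDS[4:6]),
    ("NK-219_mm-O_rf1", "recessive", COPY_IDS[6:9]),
    ("TK-81_mm-O_rf1", "recessive", COPY_IDS[9:10]),
    ("PI-615522_rf1", "recessive", COPY_IDS[10:11]),
    ("Fukkoku-ouba_rf1", "non_restoring", COPY_IDS[11:12]),
)

_NONGEN_IDX = frozenset(
    i for i, cid in enumerate(COPY_IDS) if cid not in GENERATIVE
)

# Planned polymorphisms (ancestral coordinates).  The 3-bp deletion at 150 is
# carried by every non-generative copy, i.e. generative copies share a 3-bp
# insertion usable as a class-specific primer anchor.  The 6-bp deletion at
# 250 is private to NK-198 copies 2 and 3.  SNPs at 950/962 sit in the 3'
# trailer.  Remaining SNPs give each allele (and each NK-219 member) a
# private difference.
VARIANT_PLAN = (
    PlannedVariant("deletion", 150, _NONGEN_IDX, length=3),
    PlannedVariant("deletion", 250, frozenset({1, 2}), length=6),
    PlannedVariant("snp", 500, frozenset({4, 5})),
    PlannedVariant("snp", 520, frozenset({6, 7, 8})),
    PlannedVariant("snp", 540, frozenset({9})),
    PlannedVariant("snp", 560, frozenset({10})),
    PlannedVariant("snp", 580, frozenset({11})),
    PlannedVariant("snp", 600, frozenset({6})),
    PlannedVariant("snp", 620, frozenset({7})),
    PlannedVariant("snp", 950, frozenset({3})),
    PlannedVariant("snp", 962, frozenset({2})),
)

DEFAULT_SEED = 20201103


def rf1_locus_catalog(
    seed: int = DEFAULT_SEED,
) -> tuple[list[ParalogCopy], list[RfAllele]]:
    """The full six-allele cluster (12 members, one a pseudogene)."""
    family = make_paralog_family(
        BASE_LENGTH,
        len(COPY_IDS),
        VARIANT_PLAN,
        seed=seed,
        copy_ids=list(COPY_IDS),
        features=FEATURES,
    )
    allele_of = {
        cid: allele_id for allele_id, _action, members in _ALLELES for cid in members
    }
    copies = [
        replace(
            c,
            allele_id=allele_of[c.copy_id],
            generative=c.copy_id in GENERATIVE,
            pseudogene=c.copy_id in PSEUDOGENES,
        )
        for c in family
    ]
    by_id = {c.copy_id: c for c in copies}
    alleles = [
        RfAllele(
            allele_id=allele_id,
            copies=tuple(members),
            action_label=action,
            generative_count=sum(by_id[m].generative for m in members),
        )
        for allele_id, action, members in _ALLELES
    ]
    return copies, alleles


def nk198_family(seed: int = DEFAULT_SEED) -> list[ParalogCopy]:
    """The four NK-198 *Rf1* copies (the transcript-ratio study set)."""
    copies, _ = rf1_locus_catalog(seed=seed)
    return [c for c in copies if c.allele_id == "NK-198_Rf1"]


def generative_partition(copies) -> list[set[str]]:
    """Two-block target partition: 200-kDa generative vs non-generative."""
    gen = {c.copy_id for c in copies if c.generative}
    non = {c.copy_id for c in copies if not c.generative}
    return [gen, non]
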