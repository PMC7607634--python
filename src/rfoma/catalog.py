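"""Model of an *Rf1*-style locus: clustered, near-identical paralog copies.

The sugar beet *Rf1* restorer locus is a cluster of *Oma1*-like gene copies
(*RF-Oma1*) whose composition varies between alleles.  Because the copies are
>90% identical, copy-specific quantification hinges on *diagnostic sites*:
alignment columns (SNPs) or contiguous gap runs (indels) whose allelic states
split the copies into distinguishable groups.  This module loads a copy
catalog from FASTA + TSV metadata, builds a global multiple alignment of the
copies, and scans it for such sites.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner

from .util import check_alphabet

GAP = "-"

FEATURE_KINDS = ("exon", "intron", "utr3")
ACTION_LABELS = ("dominant", "semi_dominant", "recessive", "non_restoring")


class CatalogError(ValueError):
    """Malformed catalog input (ids, sequences, metadata)."""


@dataclass(frozen=True)
class ParalogCopy:
    """One member of the paralog cluster, in transcript orientation.

    ``features`` are (kind, start, end) half-open intervals in local
    coordinates; ``generative`` marks copies whose protein can generate the
    200-kDa preSATP6-binding complex; a pseudogene is never generative.
    """

    copy_id: str
    allele_id: str
    sequence: str
    features: tuple[tuple[str, int, int], ...] = ()
    generative: bool = False
    pseudogene: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise CatalogError(f"copy {self.copy_id!r}: empty sequence")
        try:
            check_alphabet(self.sequence, f"copy {self.copy_id!r}")
        except ValueError as exc:
            raise CatalogError(str(exc)) from exc
        n = len(self.sequence)
        for kind, start, end in self.features:
            if kind not in FEATURE_KINDS:
                raise CatalogError(
                    f"copy {self.copy_id!r}: unknown feature kind {kind!r}"
                )
            if not (0 <= start < end <= n):
                raise CatalogError(
                    f"copy {self.copy_id!r}: feature {kind} [{start},{end}) "
                    f"outside [0,{n})"
                )
        if self.pseudogene and self.generative:
            raise CatalogError(
                f"copy {self.copy_id!r}: a pseudogene cannot be 200-kDa generative"
            )


@dataclass(frozen=True)
class RfAllele:
    """An allele of the locus: an ordered cluster of copy ids."""

    allele_id: str
    copies: tuple[str, ...]
    action_label: str
    generative_count: int

    def __post_init__(self) -> None:
        if not self.copies:
            raise CatalogError(f"allele {self.allele_id!r}: no member copies")
        if self.action_label not in ACTION_LABELS:
            raise CatalogError(
                f"allele {self.allele_id!r}: unknown action {self.action_label!r}"
            )


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in {"1", "true", "yes", "t"}:
        return True
    if text in {"0", "false", "no", "f", ""}:
        return False
    raise CatalogError(f"cannot interpret {value!r} as a boolean")


def _parse_features(text) -> tuple[tuple[str, int, int], ...]:
    if text is None or (isinstance(text, float) and pd.isna(text)) or text == "":
        return ()
    out = []
    for chunk in str(text).split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        kind, _, span = chunk.partition(":")
        start, _, end = span.partition("-")
        out.append((kind.strip(), int(start), int(end)))
    return tuple(out)


def format_features(features: Iterable[tuple[str, int, int]]) -> str:
    return ";".join(f"{kind}:{start}-{end}" for kind, start, end in features)


def load_catalog(
    fasta_path: str | Path, metadata_path: str | Path
) -> tuple[list[ParalogCopy], list[RfAllele]]:
    """Read copy sequences (FASTA) and their metadata (TSV) into a locus model.

    The metadata table must carry columns ``copy_id``, ``allele_id``,
    ``action_label``, ``generative``, ``pseudogene`` and optionally
    ``features`` (semicolon-separated ``kind:start-end`` intervals).  FASTA
    ids and metadata copy_ids must match one-to-one.
    """
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in seqs:
            raise CatalogError(f"duplicate FASTA id {record.id!r}")
        seqs[record.id] = str(record.seq).upper()

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
    required = {"copy_id", "allele_id", "action_label", "generative", "pseudogene"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise CatalogError(f"metadata missing columns: {sorted(missing_cols)}")
    if meta["copy_id"].duplicated().any():
        dup = meta.loc[meta["copy_id"].duplicated(), "copy_id"].tolist()
        raise CatalogError(f"duplicate metadata copy_ids: {dup}")

    orphans = sorted(set(meta["copy_id"]) - set(seqs))
    if orphans:
        raise CatalogError(f"metadata copies absent from FASTA: {orphans}")
    unlisted = sorted(set(seqs) - set(meta["copy_id"]))
    if unlisted:
        raise CatalogError(f"FASTA ids absent from metadata: {unlisted}")

    copies: list[ParalogCopy] = []
    allele_members: dict[str, list[str]] = {}
    allele_actions: dict[str, str] = {}
    for row in meta.itertuples(index=False):
        copy = ParalogCopy(
            copy_id=row.copy_id,
            allele_id=row.allele_id,
            sequence=seqs[row.copy_id],
            features=_parse_features(getattr(row, "features", "")),
            generative=_parse_bool(row.generative),
            pseudogene=_parse_bool(row.pseudogene),
        )
        copies.append(copy)
        allele_members.setdefault(row.allele_id, []).append(row.copy_id)
        allele_actions.setdefault(row.allele_id, row.action_label)

    by_id = {c.copy_id: c for c in copies}
    alleles = [
        RfAllele(
            allele_id=aid,
            copies=tuple(members),
            action_label=allele_actions[aid],
            generative_count=sum(by_id[m].generative for m in members),
        )
        for aid, members in allele_members.items()
    ]
    return copies, alleles


def write_catalog(
    copies: Sequence[ParalogCopy],
    alleles: Sequence[RfAllele],
    fasta_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Inverse of :func:`load_catalog` (plain FASTA + TSV)."""
    with open(fasta_path, "w") as fh:
        for copy in copies:
            fh.write(f">{copy.copy_id}\n{copy.sequence}\n")
    actions = {a.allele_id: a.action_label for a in alleles}
    rows = [
        {
            "copy_id": c.copy_id,
            "allele_id": c.allele_id,
            "action_label": actions.get(c.allele_id, "recessive"),
            "generative": int(c.generative),
            "pseudogene": int(c.pseudogene),
            "features": format_features(c.features),
        }
        for c in copies
    ]
    pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Multiple alignment (star progressive around a centre sequence)
# ---------------------------------------------------------------------------


@dataclass
class CopyAlignment:
    """Global alignment of all catalog copies.

    ``rows[i]`` is the gapped string for ``copy_ids[i]``; ungapping a row
    reproduces the copy's sequence exactly.  Coordinate maps between sequence
    positions and alignment columns are built eagerly.
    """

    copy_ids: list[str]
    rows: list[str]
    _pos_to_col: list[list[int]] = field(default_factory=list, repr=False)
    _col_to_pos: list[list[int | None]] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise CatalogError("empty alignment")
        ncol = len(self.rows[0])
        if any(len(r) != ncol for r in self.rows):
            raise CatalogError("alignment rows differ in length")
        self._pos_to_col = []
        self._col_to_pos = []
        for row in self.rows:
            p2c: list[int] = []
            c2p: list[int | None] = []
            pos = 0
            for col, ch in enumerate(row):
                if ch == GAP:
                    c2p.append(None)
                else:
                    p2c.append(col)
                    c2p.append(pos)
                    pos += 1
            self._pos_to_col.append(p2c)
            self._col_to_pos.append(c2p)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row_index(self, copy_id: str) -> int:
        return self.copy_ids.index(copy_id)

    def sequence(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")

    def pos_to_col(self, i: int) -> list[int]:
        """Map sequence position -> alignment column for row ``i``."""
        return self._pos_to_col[i]

    def col_to_pos(self, i: int) -> list[int | None]:
        """Map alignment column -> sequence position (None on gaps)."""
        return self._col_to_pos[i]


def _pairwise(center: str, other: str, aligner: PairwiseAligner):
    """Decompose the best global alignment of ``other`` against ``center``.

    Returns (matched, inserts) where matched[p] is the character of ``other``
    aligned to center position p (GAP if deleted) and inserts[p] is the run of
    ``other`` characters inserted before center position p (p == len(center)
    collects the tail).
    """
    aln = aligner.align(center, other)[0]
    row_c, row_o = str(aln[0]), str(aln[1])
    matched: list[str] = []
    inserts: list[str] = ["" for _ in range(len(center) + 1)]
    p = 0
    for cc, oc in zip(row_c, row_o):
        if cc == GAP:
            inserts[p] += oc
        else:
            matched.append(oc)
            p += 1
    return matched, inserts


def align_copies(
    copies: Sequence[ParalogCopy],
    match: float = 1.0,
    mismatch: float = -2.0,
    gap_open: float = -4.0,
    gap_extend: float = -0.5,
) -> CopyAlignment:
    """Global star-progressive alignment of all copies.

    Each copy is aligned pairwise (Needleman-Wunsch with affine gaps) against
    the first copy, then the pairwise alignments are merged on the shared
    centre coordinate system ("once a gap, always a gap").  Deterministic for
    fixed inputs and scoring parameters; adequate for the >90%-identical
    sequences of a paralog cluster.
    """
    if not copies:
        raise CatalogError("align_copies: no copies given")
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend

    center = copies[0].sequence
    n_center = len(center)
    decomposed = [_pairwise(center, c.sequence, aligner) for c in copies[1:]]

    ins_width = [0] * (n_center + 1)
    for _, inserts in decomposed:
        for p, run in enumerate(inserts):
            ins_width[p] = max(ins_width[p], len(run))

    def build_row(matched: list[str], inserts: list[str]) -> str:
        parts: list[str] = []
        for p in range(n_center):
            parts.append(inserts[p].ljust(ins_width[p], GAP))
            parts.append(matched[p])
        parts.append(inserts[n_center].ljust(ins_width[n_center], GAP))
        return "".join(parts)

    rows = [build_row(list(center), ["" for _ in range(n_center + 1)])]
    rows += [build_row(m, i) for m, i in decomposed]
    return CopyAlignment([c.copy_id for c in copies], rows)


# ---------------------------------------------------------------------------
# Diagnostic sites
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiagnosticSite:
    """An alignment column run whose allelic states partition the copies.

    ``states`` maps copy_id to its state string over the site columns (gap
    characters included); ``partition`` groups copies with identical states.
    Coordinates are 0-based half-open alignment columns.
    """

    site_id: str
    kind: str  # "snp" | "indel"
    column_start: int
    column_end: int
    states: Mapping[str, str]
    partition: tuple[frozenset[str], ...]
    region_label: str | None = None

    def block_of(self, copy_id: str) -> frozenset[str]:
        for block in self.partition:
            if copy_id in block:
                return block
        raise KeyError(copy_id)


def _partition_from_states(
    copy_ids: Sequence[str], states: Mapping[str, str]
) -> tuple[frozenset[str], ...]:
    groups: dict[str, list[str]] = {}
    for cid in copy_ids:
        groups.setdefault(states[cid], []).append(cid)
    # stable order: by first appearance of the state among copies
    return tuple(frozenset(members) for members in groups.values())


def _region_label(
    aln: CopyAlignment, copies_by_id: Mapping[str, ParalogCopy] | None, col: int
) -> str | None:
    """Human-readable feature tag for a column, e.g. 'exon 1' or "3' trailer"."""
    if not copies_by_id:
        return None
    for i, cid in enumerate(aln.copy_ids):
        pos = aln.col_to_pos(i)[col]
        if pos is None:
            continue
        copy = copies_by_id.get(cid)
        if copy is None:
            continue
        counters: dict[str, int] = {}
        for kind, start, end in copy.features:
            counters[kind] = counters.get(kind, 0) + 1
            if start <= pos < end:
                if kind == "utr3":
                    return "3' trailer"
                return f"{kind} {counters[kind]}"
        return None
    return None


def discover_diagnostic_sites(
    aln: CopyAlignment,
    target_partition: Sequence[Iterable[str]] | None = None,
    copies: Sequence[ParalogCopy] | None = None,
) -> list[DiagnosticSite]:
    """Scan an alignment for SNP columns and merged indel runs.

    Contiguous gap-bearing columns with identical row-gap patterns are merged
    into a single indel site (a 6-bp deletion is one site, not six).  Without
    a target, every site with >= 2 states is returned.  With a target
    partition, only sites whose induced partition refines (or equals) the
    target are kept — exactly the sites that classify every copy into its
    target block with zero errors.
    """
    ncol = aln.n_columns
    nrow = len(aln.rows)
    copies_by_id = {c.copy_id: c for c in copies} if copies else None

    if target_partition is not None:
        blocks = [frozenset(b) for b in target_partition]
        covered = set().union(*blocks) if blocks else set()
        if covered != set(aln.copy_ids) or sum(len(b) for b in blocks) != len(
            aln.copy_ids
        ):
            raise CatalogError("target partition must cover all copies disjointly")

    def gap_pattern(col: int) -> tuple[bool, ...]:
        return tuple(aln.rows[i][col] == GAP for i in range(nrow))

    def is_variant(col: int) -> bool:
        return len({aln.rows[i][col] for i in range(nrow)}) > 1

    sites: list[DiagnosticSite] = []
    col = 0
    while col < ncol:
        pattern = gap_pattern(col)
        if any(pattern):
            start = col
            while col < ncol and gap_pattern(col) == pattern:
                col += 1
            span = (start, col)
            kind = "indel"
        elif is_variant(col):
            span = (col, col + 1)
            col += 1
            kind = "snp"
        else:
            col += 1
            continue
        cs, ce = span
        states = {
            cid: aln.rows[i][cs:ce] for i, cid in enumerate(aln.copy_ids)
        }
        partition = _partition_from_states(aln.copy_ids, states)
        if len(partition) < 2:
            continue
        sites.append(
            DiagnosticSite(
                site_id=f"{kind}_{cs}_{ce}",
                kind=kind,
                column_start=cs,
                column_end=ce,
                states=states,
                partition=partition,
                region_label=_region_label(aln, copies_by_id, cs),
            )
        )

    if target_partition is not None:
        blocks = [frozenset(b) for b in target_partition]

        def refines(site: DiagnosticSite) -> bool:
            return all(
                any(sb <= tb for tb in blocks) for sb in site.partition
            )

        sites = [s for s in sites if refines(s)]
    return sites


def merge_sites(
    aln: CopyAlignment, sites: Sequence[DiagnosticSite], site_id: str | None = None
) -> DiagnosticSite:
    """Fuse several sites into one composite site with joint states.

    Used for the pair of 3' trailer SNPs that jointly split four copies into
    three groups.  The composite spans from the first to the last fused
    column; states are the concatenated per-site states.
    """
    if not sites:
        raise CatalogError("merge_sites: no sites to merge")
    ordered = sorted(sites, key=lambda s: s.column_start)
    states = {
        cid: "".join(s.states[cid] for s in ordered) for cid in aln.copy_ids
    }
    partition = _partition_from_states(aln.copy_ids, states)
    cs = ordered[0].column_start
    ce = ordered[-1].column_end
    kind = "indel" if any(s.kind == "indel" for s in ordered) else "snp"
    return DiagnosticSite(
        site_id=site_id or f"composite_{cs}_{ce}",
        kind=kind,
        column_start=cs,
        column_end=ce,
        states=states,
        partition=partition,
        region_label=ordered[0].region_label,
    )


def sites_to_table(sites: Sequence[DiagnosticSite]) -> pd.DataFrame:
    """Flat TSV-ready report of discovered sites."""
    rows = []
    for s in sites:
        rows.append(
            {
                "site_id": s.site_id,
                "kind": s.kind,
                "column_start": s.column_start,
                "column_end": s.column_end,
                "region": s.region_label or "",
                "states": ";".join(
                    f"{cid}={state}" for cid, state in sorted(s.states.items())
                ),
                "partition": " | ".join(
                    ",".join(sorted(block)) for block in s.partition
                ),
            }
        )
    return pd.DataFrame(rows)
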