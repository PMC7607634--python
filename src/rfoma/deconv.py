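"""Exact-match read classification and per-copy transcript-ratio deconvolution.

A read pair is *informative* when both mates match a proper, non-empty subset
of the paralog copies with zero mismatches — the in-silico analogue of the
"no discrepancy with each reference" counting rule.  Block counts at the
diagnostic sites are then combined arithmetically: with the exon-1 indel
splitting copies {1,4} | {2,3} and the 3' trailer SNPs splitting
{4} | {3} | {1,2},

    r4 = g4,  r3 = g3,  r1 = f14 - g4,  r2 = 1 - r1 - r3 - r4,

where f14 is the indel-block fraction and g* the trailer-block fractions.
The alternative estimate of r2, g12 - r1, is reported as a consistency gap
rather than averaged in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .catalog import CopyAlignment, DiagnosticSite, ParalogCopy, align_copies, \
    discover_diagnostic_sites, merge_sites
from .simulate import ReadPair
from .util import revcomp


class EstimationError(ValueError):
    """Insufficient depth or incompatible site structure for deconvolution."""


# ---------------------------------------------------------------------------
# Read classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadAssignment:
    """Copies a read pair matches exactly; informative = proper subset."""

    read_id: str
    matched_copies: frozenset[str]
    informative: bool
    # first consistent (mate1_start, mate2_start) per matched copy, with the
    # mate lengths; needed to decide which diagnostic sites the pair covers
    positions: Mapping[str, tuple[int, int, int, int]] = field(default_factory=dict)


def _occurrences(needle: str, haystack: str) -> list[int]:
    out = []
    start = haystack.find(needle)
    while start != -1:
        out.append(start)
        start = haystack.find(needle, start + 1)
    return out


def _match_one(
    mate1: str, mate2: str, template: str, max_fragment: int
) -> tuple[int, int] | None:
    """First (p1, p2) with mate1 sense at p1, revcomp(mate2) at p2 >= p1."""
    rc2 = revcomp(mate2)
    starts1 = _occurrences(mate1, template)
    if not starts1:
        return None
    starts2 = _occurrences(rc2, template)
    for p1 in starts1:
        for p2 in starts2:
            if p2 < p1 or p1 + len(mate1) > p2 + len(rc2):
                continue
            if p2 + len(rc2) - p1 <= max_fragment:
                return (p1, p2)
    return None


def classify_read(
    pair: ReadPair,
    copies: Sequence[ParalogCopy],
    stranded: bool = True,
    max_fragment: int = 2000,
) -> ReadAssignment:
    """Exact-substring classification of one read pair against all copies.

    Both mates must occur with zero mismatches at positions consistent with a
    single fragment (mate1 on the sense strand, mate2 reverse-complemented;
    in unstranded mode the swapped orientation is also tried).  A single
    substitution anywhere voids the match for that copy.
    """
    matched: dict[str, tuple[int, int, int, int]] = {}
    for copy in copies:
        hit = _match_one(pair.mate1, pair.mate2, copy.sequence, max_fragment)
        which = (pair.mate1, pair.mate2)
        if hit is None and not stranded:
            hit = _match_one(pair.mate2, pair.mate1, copy.sequence, max_fragment)
            which = (pair.mate2, pair.mate1)
        if hit is not None:
            p1, p2 = hit
            matched[copy.copy_id] = (p1, p2, len(which[0]), len(which[1]))
    informative = 0 < len(matched) < len(copies)
    return ReadAssignment(
        read_id=pair.read_id,
        matched_copies=frozenset(matched),
        informative=informative,
        positions=matched,
    )


# ---------------------------------------------------------------------------
# Site counting
# ---------------------------------------------------------------------------


@dataclass
class SiteCounts:
    """Informative-read counts per state block of one diagnostic site.

    ``spans`` holds, per block, the number of template positions a mate must
    cover to genotype the site on that block's haplotype (indel junctions
    need 2 positions; an n-base insertion needs n).  It feeds the optional
    read-length bias correction in :meth:`fractions`.
    """

    site_id: str
    counts: dict[frozenset[str], float]
    spans: dict[frozenset[str], int]

    @property
    def depth(self) -> float:
        return float(sum(self.counts.values()))

    def fractions(self, read_length: int | None = None) -> dict[frozenset[str], float]:
        """Block fractions, optionally corrected for haplotype span length.

        A mate of length R can cover a span of sigma positions from
        R - sigma + 1 start offsets, so deletion-haplotype reads (small
        sigma) are over-represented in raw counts; weighting each block by
        1 / (R - sigma + 1) removes that first-order bias.
        """
        if self.depth == 0:
            raise EstimationError(f"site {self.site_id}: zero informative depth")
        if read_length is None:
            total = self.depth
            return {b: c / total for b, c in self.counts.items()}
        weighted = {
            b: c / max(read_length - self.spans[b] + 1, 1)
            for b, c in self.counts.items()
        }
        total = sum(weighted.values())
        return {b: w / total for b, w in weighted.items()}

    @classmethod
    def from_fractions(
        cls,
        site_id: str,
        fractions: Mapping[frozenset[str], float],
        depth: float = 1.0,
    ) -> "SiteCounts":
        counts = {b: f * depth for b, f in fractions.items()}
        return cls(site_id=site_id, counts=counts, spans={b: 1 for b in counts})


def _block_span(aln: CopyAlignment, site: DiagnosticSite, block: frozenset[str]) -> int:
    """Template positions a mate must cover to genotype ``site`` on ``block``."""
    rep = sorted(block)[0]
    i = aln.row_index(rep)
    c2p = aln.col_to_pos(i)
    positions = [
        c2p[c] for c in range(site.column_start, site.column_end) if c2p[c] is not None
    ]
    if not positions:
        return 2  # pure deletion: the 2-bp junction
    return positions[-1] - positions[0] + 1


def _covered(intervals: list[tuple[int, int]], lo: int, hi: int) -> bool:
    """True if [lo, hi] (inclusive) is inside the union of inclusive intervals."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return any(s <= lo and hi <= e for s, e in merged)


def count_sites(
    assignments: Sequence[ReadAssignment],
    sites: Sequence[DiagnosticSite],
    aln: CopyAlignment,
    block_match: str = "exact",
) -> list[SiteCounts]:
    """Tally informative reads into site state blocks.

    A pair contributes to a site iff its matched set resolves one state block
    and the site's full column span is covered by sequenced bases of a single
    mate (mate intervals are contiguous in alignment-column space because
    matches are exact).  ``block_match="exact"`` requires the matched set to
    equal the block; ``"subset"`` also accepts reads resolved beyond the
    block by other sites (needed when pooling a single SNP of a composite).
    Requiring full-span coverage keeps the block fractions unbiased when a
    partial overlap would collapse distinct states.
    """
    if block_match not in ("exact", "subset"):
        raise ValueError(f"unknown block_match mode {block_match!r}")
    results: list[SiteCounts] = []
    for site in sites:
        blocks = {frozenset(b) for b in site.partition}
        counts: dict[frozenset[str], float] = {frozenset(b): 0.0 for b in blocks}
        spans = {b: _block_span(aln, site, b) for b in counts}
        lo, hi = site.column_start, site.column_end - 1
        for a in assignments:
            if not a.matched_copies:
                continue
            if block_match == "exact":
                if a.matched_copies not in blocks:
                    continue
                block = a.matched_copies
            else:
                containing = [b for b in blocks if a.matched_copies <= b]
                if len(containing) != 1:
                    continue
                block = containing[0]
            rep = sorted(a.matched_copies)[0]
            p1, p2, l1, l2 = a.positions[rep]
            i = aln.row_index(rep)
            p2c = aln.pos_to_col(i)
            intervals = [
                (p2c[p1], p2c[p1 + l1 - 1]),
                (p2c[p2], p2c[p2 + l2 - 1]),
            ]
            if _covered(intervals, lo, hi):
                counts[block] += 1
        results.append(SiteCounts(site_id=site.site_id, counts=counts, spans=spans))
    return results


# ---------------------------------------------------------------------------
# Ratio estimation
# ---------------------------------------------------------------------------


@dataclass
class RatioEstimate:
    """Per-copy transcript fractions for one replicate (sums to 1)."""

    replicate_id: str
    ratios: dict[str, float]
    group_fractions_used: dict[str, dict[str, float]]
    consistency_gap: float
    clipped: bool = False

    def __post_init__(self) -> None:
        total = sum(self.ratios.values())
        if abs(total - 1.0) > 1e-6:
            raise EstimationError(f"ratios sum to {total}, not 1")
        if any(r < 0 or r > 1 for r in self.ratios.values()):
            raise EstimationError("ratio outside [0, 1]")


def _fraction_key(block: frozenset[str]) -> str:
    return "+".join(sorted(block))


def estimate_copy_ratios(
    indel_counts: SiteCounts,
    utr_counts: SiteCounts,
    indel_site: DiagnosticSite,
    utr_site: DiagnosticSite,
    min_depth: float = 50,
    read_length: int | None = None,
    replicate_id: str = "rep1",
    aux_counts: SiteCounts | None = None,
) -> RatioEstimate:
    """Solve the four copy fractions from the two site block-fraction sets.

    Requires the indel site to split the copies into two doubletons and the
    trailer site into two singletons plus one doubleton, with each indel
    block containing exactly one singleton; this is the published structure.
    Negative intermediates (finite-depth noise) are clipped to 0 and the
    vector renormalized, with the clip flagged.

    The composite trailer fractions plus the indel fraction determine the
    four ratios exactly, so a redundancy check needs extra data:
    ``aux_counts`` may carry one trailer SNP counted on its own (a partially
    independent read set).  The singleton fraction re-measured there yields a
    second estimate of the arithmetically recovered copy, and
    ``consistency_gap`` is the absolute difference between the two; it
    converges to 0 with depth.  Without ``aux_counts`` the gap is 0 by
    construction.
    """
    for counts in (indel_counts, utr_counts):
        if counts.depth < min_depth:
            raise EstimationError(
                f"site {counts.site_id}: informative depth {counts.depth:.0f} "
                f"below minimum {min_depth}"
            )

    indel_blocks = [frozenset(b) for b in indel_site.partition]
    utr_blocks = [frozenset(b) for b in utr_site.partition]
    if sorted(len(b) for b in indel_blocks) != [2, 2]:
        raise EstimationError("indel site must split copies into two doubletons")
    if sorted(len(b) for b in utr_blocks) != [1, 1, 2]:
        raise EstimationError(
            "trailer site must split copies into two singletons and a doubleton"
        )

    f = indel_counts.fractions(read_length)
    g = utr_counts.fractions(read_length)

    singles = [b for b in utr_blocks if len(b) == 1]
    double = next(b for b in utr_blocks if len(b) == 2)
    (x,) = singles[0]
    (y,) = singles[1]

    block_x = next(b for b in indel_blocks if x in b)
    block_y = next(b for b in indel_blocks if y in b)
    if block_x == block_y:
        raise EstimationError("singleton copies fall in the same indel block")
    a_candidates = block_x & double
    b_candidates = block_y & double
    if len(a_candidates) != 1 or len(b_candidates) != 1:
        raise EstimationError("indel and trailer partitions are incompatible")
    (a,) = a_candidates
    (b,) = b_candidates

    r = {
        x: g[frozenset({x})],
        y: g[frozenset({y})],
    }
    r[a] = f[block_x] - r[x]
    r[b] = 1.0 - r[a] - r[x] - r[y]

    gap = 0.0
    if aux_counts is not None and aux_counts.depth > 0:
        aux_fracs = aux_counts.fractions(read_length)
        single_blocks = [blk for blk in aux_fracs if len(blk) == 1]
        aux_single = next(
            (blk for blk in single_blocks if x in blk or y in blk), None
        )
        if aux_single is not None:
            if x in aux_single:
                r_a_alt = f[block_x] - aux_fracs[aux_single]
                gap = abs((g[double] - r_a_alt) - r[b])
            else:
                r_b_alt = f[block_y] - aux_fracs[aux_single]
                gap = abs((g[double] - r[a]) - r_b_alt)

    clipped = any(v < 0 for v in r.values())
    if clipped:
        r = {k: max(v, 0.0) for k, v in r.items()}
    total = sum(r.values())
    r = {k: v / total for k, v in r.items()}

    group_fractions = {
        indel_counts.site_id: {_fraction_key(k): v for k, v in f.items()},
        utr_counts.site_id: {_fraction_key(k): v for k, v in g.items()},
    }
    return RatioEstimate(
        replicate_id=replicate_id,
        ratios=r,
        group_fractions_used=group_fractions,
        consistency_gap=gap,
        clipped=clipped,
    )


# ---------------------------------------------------------------------------
# Replicate summary (Tukey HSD with compact letter display)
# ---------------------------------------------------------------------------


@dataclass
class ReplicateSummary:
    """Across-replicate means/SDs with Tukey multiple-comparison letters."""

    means: dict[str, float]
    sds: dict[str, float]
    tukey_letters: dict[str, str]
    alpha: float


def _letters_from_graph(order: Sequence[str], ns_graph: nx.Graph) -> dict[str, str]:
    """Compact letter display: letters are maximal cliques of the
    not-significantly-different graph, lettered from the largest mean."""
    cliques = [frozenset(c) for c in nx.find_cliques(ns_graph)]
    rank = {cid: i for i, cid in enumerate(order)}
    cliques.sort(key=lambda c: min(rank[m] for m in c))
    letters: dict[str, list[str]] = {cid: [] for cid in order}
    for i, clique in enumerate(cliques):
        symbol = chr(ord("a") + i)
        for member in clique:
            letters[member].append(symbol)
    return {cid: "".join(sorted(v)) for cid, v in letters.items()}


def summarize_replicates(
    estimates: Sequence[RatioEstimate], alpha: float = 0.05
) -> ReplicateSummary:
    """Per-copy mean +- SD and Tukey HSD letter grouping across replicates.

    With zero residual variance Tukey is degenerate; following the limit
    behaviour of the test, distinct means then receive distinct letters and
    exactly equal means share one.
    """
    if not estimates:
        raise EstimationError("no replicates to summarize")
    copy_ids = sorted(estimates[0].ratios)
    for est in estimates:
        if sorted(est.ratios) != copy_ids:
            raise EstimationError("replicates cover different copy sets")

    values = {cid: [est.ratios[cid] for est in estimates] for cid in copy_ids}
    means = {cid: float(np.mean(v)) for cid, v in values.items()}
    if len(estimates) == 1:
        import warnings

        warnings.warn("single replicate: letters omitted", stacklevel=2)
        return ReplicateSummary(
            means=means, sds={cid: 0.0 for cid in copy_ids}, tukey_letters={},
            alpha=alpha,
        )
    sds = {cid: float(np.std(v, ddof=1)) for cid, v in values.items()}

    order = sorted(copy_ids, key=lambda c: -means[c])
    ns_graph = nx.Graph()
    ns_graph.add_nodes_from(copy_ids)

    residual_var = sum(np.var(v, ddof=1) for v in values.values())
    if residual_var == 0.0:
        for i, c1 in enumerate(copy_ids):
            for c2 in copy_ids[i + 1 :]:
                if means[c1] == means[c2]:
                    ns_graph.add_edge(c1, c2)
    else:
        data = np.concatenate([values[cid] for cid in copy_ids])
        groups = np.repeat(copy_ids, [len(values[cid]) for cid in copy_ids])
        result = pairwise_tukeyhsd(data, groups, alpha=alpha)
        for (g1, g2), reject in zip(
            ((result.groupsunique[i], result.groupsunique[j])
             for i, j in zip(*np.triu_indices(len(result.groupsunique), 1))),
            result.reject,
        ):
            if not reject:
                ns_graph.add_edge(g1, g2)

    letters = _letters_from_graph(order, ns_graph)
    return ReplicateSummary(means=means, sds=sds, tukey_letters=letters, alpha=alpha)


# ---------------------------------------------------------------------------
# Pipeline conveniences
# ---------------------------------------------------------------------------


def select_ratio_sites(
    sites: Sequence[DiagnosticSite], aln: CopyAlignment
) -> tuple[DiagnosticSite, DiagnosticSite]:
    """Pick the doubleton-pair indel site and build the composite trailer site.

    The trailer SNPs are fused with :func:`rfoma.catalog.merge_sites`; they
    must jointly induce a {1}|{1}|{2} partition.
    """
    indel = next(
        (
            s
            for s in sites
            if s.kind == "indel"
            and sorted(len(b) for b in s.partition) == [2, 2]
        ),
        None,
    )
    if indel is None:
        raise EstimationError("no indel site with a doubleton/doubleton partition")
    snps = [s for s in sites if s.kind == "snp"]
    if not snps:
        raise EstimationError("no SNP sites for the trailer composite")
    composite = merge_sites(aln, snps, site_id="utr_composite")
    if sorted(len(b) for b in composite.partition) != [1, 1, 2]:
        raise EstimationError(
            "SNP sites do not jointly induce a singleton/singleton/doubleton split"
        )
    return indel, composite


def deconvolve(
    copies: Sequence[ParalogCopy],
    pairs: Sequence[ReadPair],
    min_depth: float = 50,
    stranded: bool = True,
    replicate_id: str = "rep1",
    length_bias_correction: bool = True,
) -> RatioEstimate:
    """End-to-end deconvolution: align, discover sites, classify, estimate."""
    aln = align_copies(copies)
    sites = discover_diagnostic_sites(aln, copies=copies)
    indel, utr = select_ratio_sites(sites, aln)
    assignments = [classify_read(p, copies, stranded=stranded) for p in pairs]
    indel_counts, utr_counts = count_sites(assignments, [indel, utr], aln)
    # one trailer SNP re-counted on its own (subset matching) feeds the
    # consistency gap with a partially independent read set
    single_snp = next(
        (
            s
            for s in sites
            if s.kind == "snp" and sorted(len(b) for b in s.partition)[0] == 1
        ),
        None,
    )
    aux = (
        count_sites(assignments, [single_snp], aln, block_match="subset")[0]
        if single_snp is not None
        else None
    )
    read_length = len(pairs[0].mate1) if (pairs and length_bias_correction) else None
    return estimate_copy_ratios(
        indel_counts,
        utr_counts,
        indel,
        utr,
        min_depth=min_depth,
        read_length=read_length,
        replicate_id=replicate_id,
        aux_counts=aux,
    )


def assignments_table(assignments: Sequence[ReadAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [a.read_id for a in assignments],
            "matched_copies": [
                ",".join(sorted(a.matched_copies)) for a in assignments
            ],
            "informative": [a.informative for a in assignments],
        }
    )


def counts_table(counts: Sequence[SiteCounts]) -> pd.DataFrame:
    rows = []
    for sc in counts:
        for block, value in sc.counts.items():
            rows.append(
                {
                    "site_id": sc.site_id,
                    "block": _fraction_key(block),
                    "count": value,
                    "depth": sc.depth,
                }
            )
    return pd.DataFrame(rows)
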