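"""Copy-class-discriminating primer design and in-silico PCR.

The discrimination mechanism is an indel under a primer's 3' terminus: a
primer whose 3' end spans the indel matches full-length only on copies
carrying the target state, so exact-match binding (0 mismatches, the
default) directly encodes specificity.  Melting temperatures use the Wallace
rule (2 deg C per A/T + 4 deg C per G/C).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .catalog import CopyAlignment, DiagnosticSite, ParalogCopy
from .util import check_alphabet, revcomp


class DesignError(RuntimeError):
    """No primer pair satisfying the constraints exists."""


@dataclass(frozen=True)
class PrimerPair:
    """A discriminating primer set, both primers written 5'->3'."""

    forward: str
    reverse: str
    max_product_length: int
    label: str = ""

    def __post_init__(self) -> None:
        check_alphabet(self.forward, "forward primer")
        check_alphabet(self.reverse, "reverse primer")


@dataclass(frozen=True)
class AmpliconPrediction:
    """Predicted products of one primer pair on one template copy."""

    copy_id: str
    products: tuple[tuple[int, int, int], ...]  # (start, end, length)

    @property
    def amplifies(self) -> bool:
        return bool(self.products)


def wallace_tm(primer: str) -> float:
    """Wallace-rule melting temperature in deg C."""
    at = sum(primer.count(b) for b in "AT")
    gc = sum(primer.count(b) for b in "GC")
    return 2.0 * at + 4.0 * gc


def find_binding_sites(primer: str, template: str) -> list[tuple[int, str]]:
    """Exact full-length annealing positions on both strands.

    Plus-strand hits are occurrences of the primer itself; minus-strand hits
    are occurrences of its reverse complement (position reported on the plus
    strand, 0-based leftmost).
    """
    hits: list[tuple[int, str]] = []
    for needle, strand in ((primer, "+"), (revcomp(primer), "-")):
        start = template.find(needle)
        while start != -1:
            hits.append((start, strand))
            start = template.find(needle, start + 1)
    return sorted(hits)


def predict_amplicons(
    pair: PrimerPair, copies: Sequence[ParalogCopy]
) -> list[AmpliconPrediction]:
    """Enumerate all products of the pair on every catalog copy.

    A product exists wherever a plus-strand forward site lies upstream of a
    minus-strand reverse site and the span does not exceed
    ``max_product_length``.
    """
    out = []
    for copy in copies:
        fwd = [p for p, s in find_binding_sites(pair.forward, copy.sequence) if s == "+"]
        rev = [p for p, s in find_binding_sites(pair.reverse, copy.sequence) if s == "-"]
        products = []
        for f in fwd:
            for r in rev:
                end = r + len(pair.reverse)
                length = end - f
                if f <= r and 0 < length <= pair.max_product_length:
                    products.append((f, end, length))
        out.append(AmpliconPrediction(copy_id=copy.copy_id, products=tuple(products)))
    return out


def _invariant_runs(aln: CopyAlignment, start_col: int) -> list[tuple[int, int]]:
    """Maximal runs of columns >= start_col identical and gap-free in all rows."""
    runs: list[tuple[int, int]] = []
    ncol = aln.n_columns
    col = start_col
    while col < ncol:
        chars = {row[col] for row in aln.rows}
        if len(chars) == 1 and "-" not in chars:
            run_start = col
            while col < ncol:
                chars = {row[col] for row in aln.rows}
                if len(chars) != 1 or "-" in chars:
                    break
                col += 1
            runs.append((run_start, col))
        else:
            col += 1
    return runs


def design_discriminating_primers(
    aln: CopyAlignment,
    site: DiagnosticSite,
    target_block: frozenset[str] | set[str],
    copies: Sequence[ParalogCopy],
    min_length: int = 18,
    max_length: int = 25,
    tm_min: float = 50.0,
    tm_max: float = 65.0,
    max_product_length: int = 1500,
    label: str = "discriminating",
) -> PrimerPair:
    """Design a pair amplifying exactly the target block of an indel site.

    The forward primer's 3' terminus is anchored 1-4 bases past the indel so
    that its full-length sequence exists only on target-block copies; the
    reverse primer sits in a downstream invariant region.  Every candidate is
    verified with :func:`predict_amplicons` before being returned.
    """
    target = frozenset(target_block)
    if site.kind != "indel":
        raise DesignError("discriminating design requires an indel site")
    if target not in {frozenset(b) for b in site.partition}:
        raise DesignError(
            "target_block must be one state block of the site "
            f"(got {sorted(target)})"
        )
    by_id = {c.copy_id: c for c in copies}
    if set(aln.copy_ids) != set(by_id):
        raise DesignError("alignment and copy catalog cover different copies")

    rep = sorted(target)[0]
    i = aln.row_index(rep)
    seq = aln.sequence(i)
    c2p = aln.col_to_pos(i)

    # first template position at/after the indel's right edge
    pos_after = next(
        (c2p[c] for c in range(site.column_end, aln.n_columns) if c2p[c] is not None),
        None,
    )
    # last template position before the indel's left edge
    pos_before = next(
        (
            c2p[c]
            for c in range(site.column_start - 1, -1, -1)
            if c2p[c] is not None
        ),
        None,
    )
    if pos_after is None or pos_before is None:
        raise DesignError("indel site touches the template boundary")

    non_target = [c for c in copies if c.copy_id not in target]

    for overhang in (1, 2, 3, 4):
        end = pos_after + overhang  # exclusive 3' end of forward primer
        if end > len(seq):
            continue
        for length in range(min_length, max_length + 1):
            start = end - length
            if start < 0 or start > pos_before:
                continue  # must span the indel
            forward = seq[start:end]
            if not (tm_min <= wallace_tm(forward) <= tm_max):
                continue
            if any(forward in c.sequence for c in non_target):
                continue
            if not all(forward in by_id[cid].sequence for cid in target):
                continue
            pair = _place_reverse(
                aln, site, forward, start, end, target, copies,
                min_length, max_length, tm_min, tm_max, max_product_length, label,
            )
            if pair is not None:
                return pair
    raise DesignError(
        f"no specific primer pair found for block {sorted(target)} "
        f"at site {site.site_id}"
    )


def _place_reverse(
    aln: CopyAlignment,
    site: DiagnosticSite,
    forward: str,
    fwd_start: int,
    fwd_end: int,
    target: frozenset[str],
    copies: Sequence[ParalogCopy],
    min_length: int,
    max_length: int,
    tm_min: float,
    tm_max: float,
    max_product_length: int,
    label: str,
) -> PrimerPair | None:
    rep = sorted(target)[0]
    i = aln.row_index(rep)
    seq = aln.sequence(i)
    p2c = aln.pos_to_col(i)
    c2p = aln.col_to_pos(i)

    for run_start, run_end in _invariant_runs(aln, p2c[fwd_end - 1] + 1):
        for length in range(min_length, max_length + 1):
            if run_end - run_start < length:
                continue
            window = (run_start, run_start + length)
            w_start = c2p[window[0]]
            w_end = c2p[window[1] - 1] + 1
            product_len = w_end - fwd_start
            if product_len > max_product_length:
                break
            reverse = revcomp(seq[w_start:w_end])
            if not (tm_min <= wallace_tm(reverse) <= tm_max):
                continue
            pair = PrimerPair(
                forward=forward,
                reverse=reverse,
                max_product_length=max_product_length,
                label=label,
            )
            predictions = predict_amplicons(pair, copies)
            amplified = {p.copy_id for p in predictions if p.amplifies}
            if amplified == set(target):
                return pair
    return None


def primer_report(
    pair: PrimerPair, copies: Sequence[ParalogCopy]
) -> pd.DataFrame:
    """TSV-ready per-copy specificity report for a primer pair."""
    predictions = predict_amplicons(pair, copies)
    rows = []
    for p in predictions:
        rows.append(
            {
                "label": pair.label,
                "forward": pair.forward,
                "reverse": pair.reverse,
                "tm_forward": wallace_tm(pair.forward),
                "tm_reverse": wallace_tm(pair.reverse),
                "copy_id": p.copy_id,
                "amplifies": p.amplifies,
                "product_lengths": ",".join(str(x[2]) for x in p.products),
            }
        )
    return pd.DataFrame(rows)


def marker_pattern(
    pair: PrimerPair, copies: Sequence[ParalogCopy]
) -> dict[str, tuple[int, ...]]:
    """Expected amplicon-length multiset per allele (s17-style size marker)."""
    predictions = {p.copy_id: p for p in predict_amplicons(pair, copies)}
    patterns: dict[str, list[int]] = {}
    for copy in copies:
        lengths = [x[2] for x in predictions[copy.copy_id].products]
        patterns.setdefault(copy.allele_id, []).extend(lengths)
    return {allele: tuple(sorted(v)) for allele, v in patterns.items()}
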