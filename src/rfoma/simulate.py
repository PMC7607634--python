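"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: a family of
near-identical paralog transcripts carrying planned indels/SNPs, stranded
101-bp paired-end reads drawn from a transcript mixture, replicated blot
densitometry ratios, and qPCR Ct tables.  All generators are deterministic
for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import ParalogCopy
from .util import ALPHABET, random_seq, revcomp


class SimulationError(ValueError):
    """Invalid simulation specification."""


# ---------------------------------------------------------------------------
# Paralog family generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlannedVariant:
    """A planned polymorphism shared by a subset of copies.

    ``kind`` is "snp" (single-base substitution, ``alt`` optional) or
    "deletion" (``length`` bases removed in the member copies).  ``position``
    and ``length`` are on the ancestral base sequence; ``copies`` holds
    0-based copy indices carrying the variant.
    """

    kind: str
    position: int
    copies: frozenset[int]
    length: int = 1
    alt: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("snp", "deletion"):
            raise SimulationError(f"unknown variant kind {self.kind!r}")
        if self.kind == "snp" and self.length != 1:
            raise SimulationError("snp variants have length 1")
        if self.length < 1 or self.position < 0:
            raise SimulationError("variant position/length out of range")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.position, self.position + self.length)


def _shift(x: int, deletions: Sequence[tuple[int, int]]) -> int:
    """Base coordinate -> copy coordinate given the copy's deletions."""
    return x - sum(min(e, x) - s for s, e in deletions if s < x)


def make_paralog_family(
    base_length: int,
    n_copies: int,
    variant_plan: Sequence[PlannedVariant],
    seed: int,
    copy_ids: Sequence[str] | None = None,
    allele_id: str = "simA",
    features: Sequence[tuple[str, int, int]] | None = None,
) -> list[ParalogCopy]:
    """Generate ``n_copies`` transcripts identical except at planned variants.

    The ancestral sequence is uniform random from ``seed``; a SNP without an
    explicit ``alt`` substitutes the next base in A->C->G->T rotation, so the
    plan alone fixes the polymorphism structure.  Template ``features`` are
    given in ancestral coordinates and shifted per copy around deletions.
    """
    intervals = sorted(v.interval for v in variant_plan)
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise SimulationError(
                f"overlapping planned variants at [{s1},{e1}) and [{s2},{e2})"
            )
    if intervals and intervals[-1][1] > base_length:
        raise SimulationError("planned variant extends past base_length")
    for v in variant_plan:
        if any(i < 0 or i >= n_copies for i in v.copies):
            raise SimulationError("variant copy index out of range")

    rng = np.random.default_rng(seed)
    base = random_seq(rng, base_length)
    if copy_ids is None:
        copy_ids = [f"copy{i + 1}" for i in range(n_copies)]
    if len(copy_ids) != n_copies:
        raise SimulationError("copy_ids length must equal n_copies")

    out: list[ParalogCopy] = []
    for i in range(n_copies):
        chars = list(base)
        dels: list[tuple[int, int]] = []
        for v in variant_plan:
            if i not in v.copies:
                continue
            if v.kind == "snp":
                ref = base[v.position]
                alt = v.alt or ALPHABET[(ALPHABET.index(ref) + 1) % 4]
                if alt == ref:
                    raise SimulationError(
                        f"snp alt equals reference base at {v.position}"
                    )
                chars[v.position] = alt
            else:
                dels.append(v.interval)
        for s, e in sorted(dels, reverse=True):
            del chars[s:e]
        shifted = (
            tuple(
                (kind, _shift(s, dels), _shift(e, dels))
                for kind, s, e in features
            )
            if features
            else ()
        )
        out.append(
            ParalogCopy(
                copy_id=copy_ids[i],
                allele_id=allele_id,
                sequence="".join(chars),
                features=shifted,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Paired-end read simulator
# ---------------------------------------------------------------------------


@dataclass
class MixtureSpec:
    """Transcript mixture and library geometry for read simulation.

    Defaults emulate a stranded TruSeq-style library sequenced 2x101 bp.
    """

    proportions: Mapping[str, float]
    depth: int
    read_length: int = 101
    fragment_length_mean: float = 300.0
    fragment_length_sd: float = 50.0
    error_rate: float = 0.0
    stranded: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        total = float(sum(self.proportions.values()))
        if abs(total - 1.0) > 1e-9:
            raise SimulationError(f"proportions sum to {total}, not 1")
        if any(p < 0 for p in self.proportions.values()):
            raise SimulationError("negative mixture proportion")
        if self.depth <= 0:
            raise SimulationError("depth must be positive")
        if not (0.0 <= self.error_rate < 1.0):
            raise SimulationError("error_rate must be in [0, 1)")


@dataclass(frozen=True)
class ReadPair:
    """A simulated fragment with its ground-truth source copy."""

    read_id: str
    mate1: str
    mate2: str
    true_copy: str
    true_positions: tuple[int, int]


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def simulate_reads(
    copies: Sequence[ParalogCopy], spec: MixtureSpec
) -> list[ReadPair]:
    """Draw stranded paired-end reads from a transcript mixture.

    Per-copy pair counts are multinomial in the mixture proportions; fragment
    starts are uniform; fragment lengths are Gaussian, resampled (retry cap
    10) then clamped into [read_length, transcript length]; mate1 carries the
    transcript sense strand and mate2 the reverse complement; substitution
    errors are i.i.d. per base.  Ground-truth copy and fragment interval are
    embedded in the read name.
    """
    seqs = {c.copy_id: c.sequence for c in copies}
    order = list(spec.proportions)
    unknown = [cid for cid in order if cid not in seqs]
    if unknown:
        raise SimulationError(f"mixture names unknown copies: {unknown}")
    for cid in order:
        if len(seqs[cid]) < spec.read_length:
            raise SimulationError(
                f"transcript {cid} shorter than read_length {spec.read_length}"
            )

    rng = np.random.default_rng(spec.seed)
    counts = rng.multinomial(spec.depth, [spec.proportions[c] for c in order])

    pairs: list[ReadPair] = []
    serial = 0
    for cid, n_pairs in zip(order, counts):
        seq = seqs[cid]
        length = len(seq)
        for _ in range(n_pairs):
            flen = 0
            for _try in range(10):
                flen = int(round(rng.normal(spec.fragment_length_mean,
                                            spec.fragment_length_sd)))
                if spec.read_length <= flen <= length:
                    break
            flen = min(max(flen, spec.read_length), length)
            start = int(rng.integers(0, length - flen + 1))
            frag = seq[start : start + flen]
            mate1 = _mutate(frag[: spec.read_length], rng, spec.error_rate)
            mate2 = _mutate(revcomp(frag)[: spec.read_length], rng, spec.error_rate)
            if not spec.stranded and rng.random() < 0.5:
                mate1, mate2 = mate2, mate1
            pairs.append(
                ReadPair(
                    read_id=f"{cid}|{serial}|{start}-{start + flen}",
                    mate1=mate1,
                    mate2=mate2,
                    true_copy=cid,
                    true_positions=(start, start + flen),
                )
            )
            serial += 1
    return pairs


def write_fastq(pairs: Sequence[ReadPair], prefix: str | Path) -> tuple[Path, Path]:
    """Write mates to ``<prefix>_R1.fastq`` / ``<prefix>_R2.fastq``."""
    prefix = Path(prefix)
    p1 = prefix.with_name(prefix.name + "_R1.fastq")
    p2 = prefix.with_name(prefix.name + "_R2.fastq")
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for pair in pairs:
            f1.write(f"@{pair.read_id}/1\n{pair.mate1}\n+\n{'I' * len(pair.mate1)}\n")
            f2.write(f"@{pair.read_id}/2\n{pair.mate2}\n+\n{'I' * len(pair.mate2)}\n")
    return p1, p2


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    """Load mates back into ReadPair objects (truth fields parsed if present)."""
    from Bio import SeqIO

    out: list[ReadPair] = []
    for r1, r2 in zip(
        SeqIO.parse(str(path1), "fastq"), SeqIO.parse(str(path2), "fastq")
    ):
        rid = r1.id.rsplit("/", 1)[0]
        true_copy = rid.split("|")[0] if "|" in rid else ""
        span = (0, 0)
        if "|" in rid:
            try:
                s, e = rid.split("|")[2].split("-")
                span = (int(s), int(e))
            except (IndexError, ValueError):
                pass
        out.append(ReadPair(rid, str(r1.seq), str(r2.seq), true_copy, span))
    return out


# ---------------------------------------------------------------------------
# Densitometry and qPCR simulators
# ---------------------------------------------------------------------------


@dataclass
class DensitometrySpec:
    """Replicated 250-kDa/420-kDa blot intensity ratios per genotype.

    Each entry is (genotype_label, mean_ratio, sd, n_replicates, detected);
    an undetected genotype emits exactly 0 for every replicate.
    """

    genotypes: Sequence[tuple[str, float, float, int, bool]]
    seed: int = 0

    def __post_init__(self) -> None:
        for label, mean, sd, n, _det in self.genotypes:
            if mean < 0 or sd < 0 or n < 1:
                raise SimulationError(f"invalid densitometry spec for {label!r}")


def simulate_densitometry(spec: DensitometrySpec) -> pd.DataFrame:
    """Truncated-Gaussian intensity ratios (ratios cannot be negative)."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for label, mean, sd, n, detected in spec.genotypes:
        if not detected:
            values = np.zeros(n)
        elif sd == 0:
            values = np.full(n, mean)
        else:
            values = stats.truncnorm.rvs(
                -mean / sd, np.inf, loc=mean, scale=sd, size=n, random_state=rng
            )
        for rep, value in enumerate(values, start=1):
            rows.append(
                {
                    "genotype": label,
                    "replicate": rep,
                    "ratio_250_over_420": float(value),
                }
            )
    return pd.DataFrame(rows)


NO_AMPLIFICATION = float("nan")  # sentinel Ct for "Not detected"


@dataclass
class QpcrSpec:
    """RT-qPCR Ct pairs per genotype/stage/reference gene.

    Each sample is (genotype_label, stage, reference_gene,
    true_relative_abundance, ct_noise_sd, n_replicates).  Noise is Gaussian
    on the Ct scale; zero abundance yields the no-amplification sentinel.
    """

    samples: Sequence[tuple[str, str, str, float, float, int]]
    reference_ct_base: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        for label, _stage, _ref, abundance, sd, n in self.samples:
            if abundance < 0 or sd < 0 or n < 1:
                raise SimulationError(f"invalid qPCR spec for {label!r}")


def simulate_qpcr(spec: QpcrSpec) -> pd.DataFrame:
    """Ct tables with ct_target = ct_reference - log2(abundance) + noise."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for label, stage, ref_gene, abundance, sd, n in spec.samples:
        for rep in range(1, n + 1):
            ct_ref = spec.reference_ct_base
            if abundance == 0:
                ct_t = NO_AMPLIFICATION
            else:
                noise = rng.normal(0.0, sd) if sd > 0 else 0.0
                ct_t = ct_ref - float(np.log2(abundance)) + noise
            rows.append(
                {
                    "genotype": label,
                    "stage": stage,
                    "reference_gene": ref_gene,
                    "replicate": rep,
                    "ct_target": ct_t,
                    "ct_reference": ct_ref,
                }
            )
    return pd.DataFrame(rows)
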