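"""Exact-match classification, site counting, ratio estimation, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rfoma.catalog import DiagnosticSite, align_copies, discover_diagnostic_sites
from rfoma.deconv import (
    EstimationError,
    RatioEstimate,
    SiteCounts,
    classify_read,
    count_sites,
    deconvolve,
    estimate_copy_ratios,
    select_ratio_sites,
    summarize_replicates,
)
from rfoma.simulate import (
    MixtureSpec,
    PlannedVariant,
    ReadPair,
    make_paralog_family,
    simulate_reads,
)
from rfoma.util import revcomp

from conftest import NK198_RATIO_MEANS, NK198_RATIO_REPLICATES


# ---------------------------------------------------------------------------
# Read classification
# ---------------------------------------------------------------------------


def _oracle_matches(pair, copies, max_fragment=2000):
    """All-positions slicing oracle for exact paired matching."""
    matched = set()
    for copy in copies:
        seq = copy.sequence
        rc2 = revcomp(pair.mate2)
        ok = False
        for p1 in range(len(seq) - len(pair.mate1) + 1):
            if seq[p1 : p1 + len(pair.mate1)] != pair.mate1:
                continue
            for p2 in range(p1, len(seq) - len(rc2) + 1):
                if seq[p2 : p2 + len(rc2)] != rc2:
                    continue
                if p1 + len(pair.mate1) > p2 + len(rc2):
                    continue
                if p2 + len(rc2) - p1 <= max_fragment:
                    ok = True
                    break
            if ok:
                break
        if ok:
            matched.add(copy.copy_id)
    return matched


class TestClassifyRead:
    def test_agrees_with_bruteforce_oracle(self, nk198_copies):
        spec = MixtureSpec(
            proportions=NK198_RATIO_MEANS, depth=300, seed=21, error_rate=0.01
        )
        for pair in simulate_reads(nk198_copies, spec):
            assignment = classify_read(pair, nk198_copies)
            assert assignment.matched_copies == _oracle_matches(pair, nk198_copies)

    def test_single_substitution_discards_single_copy_match(self):
        copies = make_paralog_family(400, 1, [], seed=8)
        spec = MixtureSpec(proportions={"copy1": 1.0}, depth=5, seed=8)
        pair = simulate_reads(copies, spec)[0]
        mutated = list(pair.mate1)
        mutated[50] = {"A": "C", "C": "G", "G": "T", "T": "A"}[mutated[50]]
        bad = ReadPair(pair.read_id, "".join(mutated), pair.mate2,
                       pair.true_copy, pair.true_positions)
        assignment = classify_read(bad, copies)
        assert assignment.matched_copies == frozenset()

    def test_invariant_region_read_matches_all_copies(self, nk198_copies):
        # a fragment from the invariant region between the indel and trailer
        seq = nk198_copies[0].sequence
        frag = seq[700:850]
        pair = ReadPair("inv", frag[:101], revcomp(frag)[:101], "x", (700, 850))
        assignment = classify_read(pair, nk198_copies)
        assert assignment.matched_copies == frozenset(
            c.copy_id for c in nk198_copies
        )
        assert not assignment.informative

    def test_indel_spanning_read_matches_its_group(self, nk198_copies):
        by_id = {c.copy_id: c for c in nk198_copies}
        seq = by_id["orf20_NK-198-1"].sequence  # carries the 6-bp insertion
        frag = seq[200:420]
        pair = ReadPair("ind", frag[:101], revcomp(frag)[:101], "x", (200, 420))
        assignment = classify_read(pair, nk198_copies)
        assert assignment.matched_copies == frozenset(
            {"orf20_NK-198-1", "orf20_NK-198-4"}
        )

    def test_unstranded_mode_accepts_swapped_mates(self, nk198_copies):
        spec = MixtureSpec(proportions=NK198_RATIO_MEANS, depth=5, seed=2)
        pair = simulate_reads(nk198_copies, spec)[0]
        swapped = ReadPair(pair.read_id, pair.mate2, pair.mate1,
                           pair.true_copy, pair.true_positions)
        assert classify_read(swapped, nk198_copies).matched_copies == frozenset()
        unstranded = classify_read(swapped, nk198_copies, stranded=False)
        assert pair.true_copy in unstranded.matched_copies


# ---------------------------------------------------------------------------
# Site counting
# ---------------------------------------------------------------------------


class TestCountSites:
    def test_uninformative_reads_leave_sites_empty(self, nk198_copies):
        aln = align_copies(nk198_copies)
        sites = discover_diagnostic_sites(aln)
        indel, utr = select_ratio_sites(sites, aln)
        seq = nk198_copies[0].sequence
        frag = seq[700:850]
        pairs = [
            ReadPair(f"r{i}", frag[:101], revcomp(frag)[:101], "x", (700, 850))
            for i in range(100)
        ]
        assignments = [classify_read(p, nk198_copies) for p in pairs]
        counts = count_sites(assignments, [indel, utr], aln)
        assert all(c.depth == 0 for c in counts)

    def test_block_fractions_track_truth_within_three_sd(self, nk198_copies):
        spec = MixtureSpec(proportions=NK198_RATIO_MEANS, depth=6000, seed=13)
        pairs = simulate_reads(nk198_copies, spec)
        aln = align_copies(nk198_copies)
        indel, utr = select_ratio_sites(discover_diagnostic_sites(aln), aln)
        assignments = [classify_read(p, nk198_copies) for p in pairs]
        counts = count_sites(assignments, [indel, utr], aln)
        indel_fracs = counts[0].fractions(read_length=101)
        block_14 = frozenset({"orf20_NK-198-1", "orf20_NK-198-4"})
        truth = NK198_RATIO_MEANS["orf20_NK-198-1"] + NK198_RATIO_MEANS["orf20_NK-198-4"]
        depth = counts[0].depth
        sd = np.sqrt(truth * (1 - truth) / depth)
        assert abs(indel_fracs[block_14] - truth) <= 3 * sd


# ---------------------------------------------------------------------------
# Ratio estimation
# ---------------------------------------------------------------------------

COPYIDS = ("n1", "n2", "n3", "n4")
INDEL_BLOCKS = (frozenset({"n1", "n4"}), frozenset({"n2", "n3"}))
UTR_BLOCKS = (frozenset({"n4"}), frozenset({"n3"}), frozenset({"n1", "n2"}))

INDEL_SITE = DiagnosticSite(
    site_id="indel", kind="indel", column_start=10, column_end=16,
    states={"n1": "AACCTT", "n4": "AACCTT", "n2": "------", "n3": "------"},
    partition=INDEL_BLOCKS,
)
UTR_SITE = DiagnosticSite(
    site_id="utr", kind="snp", column_start=90, column_end=103,
    states={"n4": "GA", "n3": "AT", "n1": "AA", "n2": "AA"},
    partition=UTR_BLOCKS,
)


def _counts_from_truth(r):
    """Exact group fractions implied by a truth vector (r1, r2, r3, r4)."""
    r1, r2, r3, r4 = r
    indel = SiteCounts.from_fractions(
        "indel", {INDEL_BLOCKS[0]: r1 + r4, INDEL_BLOCKS[1]: r2 + r3}
    )
    utr = SiteCounts.from_fractions(
        "utr",
        {UTR_BLOCKS[0]: r4, UTR_BLOCKS[1]: r3, UTR_BLOCKS[2]: r1 + r2},
    )
    return indel, utr


class TestEstimateCopyRatios:
    def test_published_replicate_one_group_fractions(self):
        indel = SiteCounts.from_fractions(
            "indel", {INDEL_BLOCKS[0]: 0.45, INDEL_BLOCKS[1]: 0.55}
        )
        utr = SiteCounts.from_fractions(
            "utr", {UTR_BLOCKS[0]: 0.25, UTR_BLOCKS[1]: 0.16, UTR_BLOCKS[2]: 0.59}
        )
        est = estimate_copy_ratios(indel, utr, INDEL_SITE, UTR_SITE, min_depth=0)
        assert est.ratios["n1"] == pytest.approx(0.20, abs=1e-12)
        assert est.ratios["n2"] == pytest.approx(0.39, abs=1e-12)
        assert est.ratios["n3"] == pytest.approx(0.16, abs=1e-12)
        assert est.ratios["n4"] == pytest.approx(0.25, abs=1e-12)

    def test_symmetric_mixture_is_uniform(self):
        indel, utr = _counts_from_truth((0.25, 0.25, 0.25, 0.25))
        est = estimate_copy_ratios(indel, utr, INDEL_SITE, UTR_SITE, min_depth=0)
        assert all(v == pytest.approx(0.25, abs=1e-12) for v in est.ratios.values())
        assert est.consistency_gap == 0.0

    def test_identity_on_exact_fractions(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            truth = rng.dirichlet(np.ones(4))
            indel, utr = _counts_from_truth(truth)
            est = estimate_copy_ratios(
                indel, utr, INDEL_SITE, UTR_SITE, min_depth=0
            )
            recovered = [est.ratios[c] for c in COPYIDS]
            assert np.allclose(recovered, truth, atol=1e-9)
            assert not est.clipped

    def test_low_depth_errors_name_the_site(self):
        indel, utr = _counts_from_truth((0.2, 0.3, 0.3, 0.2))
        with pytest.raises(EstimationError, match="indel"):
            estimate_copy_ratios(indel, utr, INDEL_SITE, UTR_SITE, min_depth=50)

    def test_incompatible_partitions_rejected(self):
        bad_utr = DiagnosticSite(
            site_id="bad", kind="snp", column_start=0, column_end=1,
            states={"n1": "A", "n2": "C", "n3": "G", "n4": "T"},
            partition=(
                frozenset({"n1"}), frozenset({"n2"}),
                frozenset({"n3"}), frozenset({"n4"}),
            ),
        )
        indel, _ = _counts_from_truth((0.25, 0.25, 0.25, 0.25))
        utr = SiteCounts.from_fractions(
            "bad",
            {frozenset({"n1"}): 0.25, frozenset({"n2"}): 0.25,
             frozenset({"n3"}): 0.25, frozenset({"n4"}): 0.25},
        )
        with pytest.raises(EstimationError):
            estimate_copy_ratios(indel, utr, INDEL_SITE, bad_utr, min_depth=0)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        f14=st.floats(0.01, 0.99),
        g4=st.floats(0.01, 0.97),
        g3=st.floats(0.01, 0.97),
    )
    def test_adversarial_fractions_stay_on_simplex(self, f14, g4, g3):
        # arbitrary, possibly inconsistent group fractions: output must still
        # be a probability vector, with clipping flagged when needed
        if g4 + g3 >= 0.99:
            g_total = g4 + g3
            g4, g3 = 0.97 * g4 / g_total, 0.97 * g3 / g_total
        g12 = 1.0 - g4 - g3
        indel = SiteCounts.from_fractions(
            "indel", {INDEL_BLOCKS[0]: f14, INDEL_BLOCKS[1]: 1 - f14}
        )
        utr = SiteCounts.from_fractions(
            "utr", {UTR_BLOCKS[0]: g4, UTR_BLOCKS[1]: g3, UTR_BLOCKS[2]: g12}
        )
        est = estimate_copy_ratios(indel, utr, INDEL_SITE, UTR_SITE, min_depth=0)
        assert sum(est.ratios.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(0.0 <= v <= 1.0 for v in est.ratios.values())
        if f14 < g4:  # r1 forced negative
            assert est.clipped


# ---------------------------------------------------------------------------
# End-to-end recovery and the consistency gap
# ---------------------------------------------------------------------------


class TestEndToEnd:
    def test_recovery_at_moderate_depth(self, nk198_copies):
        # mean over 3 seeds at depth 5000: per-copy sampling SE is ~0.02 per
        # seed, so a 0.03 bound on the mean error catches systematic bias
        # (the tight 10-seed/20k-pair bound lives in the acceptance suite)
        errors = {cid: [] for cid in NK198_RATIO_MEANS}
        for seed in (97, 98, 99):
            spec = MixtureSpec(
                proportions=NK198_RATIO_MEANS, depth=5000, seed=seed, error_rate=0.001
            )
            pairs = simulate_reads(nk198_copies, spec)
            est = deconvolve(nk198_copies, pairs)
            for cid, truth in NK198_RATIO_MEANS.items():
                errors[cid].append(est.ratios[cid] - truth)
        for cid, errs in errors.items():
            assert abs(float(np.mean(errs))) < 0.03, f"{cid}: {errs}"

    def test_consistency_gap_decreases_with_depth(self, nk198_copies):
        mean_gaps = []
        for depth in (100, 1000, 10_000):
            gaps = []
            for seed in range(5):
                spec = MixtureSpec(
                    proportions=NK198_RATIO_MEANS, depth=depth, seed=seed
                )
                pairs = simulate_reads(nk198_copies, spec)
                est = deconvolve(nk198_copies, pairs, min_depth=1)
                gaps.append(est.consistency_gap)
            mean_gaps.append(float(np.mean(gaps)))
        assert mean_gaps[0] > mean_gaps[1] > mean_gaps[2]


# ---------------------------------------------------------------------------
# Replicate summary
# ---------------------------------------------------------------------------


def _estimates_from_columns(columns):
    """Build per-replicate RatioEstimate objects from printed ratio columns."""
    n_rep = len(next(iter(columns.values())))
    out = []
    for rep in range(n_rep):
        ratios = {cid: columns[cid][rep] for cid in columns}
        out.append(
            RatioEstimate(
                replicate_id=f"N{rep + 1}",
                ratios=ratios,
                group_fractions_used={},
                consistency_gap=0.0,
            )
        )
    return out


class TestSummarizeReplicates:
    def test_published_replicates_reproduce_means_and_letters(self):
        summary = summarize_replicates(_estimates_from_columns(NK198_RATIO_REPLICATES))
        rounded = {cid: round(m, 2) for cid, m in summary.means.items()}
        assert rounded == NK198_RATIO_MEANS
        letters = summary.tukey_letters
        assert letters["orf20_NK-198-2"] == "a"
        assert letters["orf20_NK-198-4"] == "b"
        assert letters["orf20_NK-198-1"] == "c"
        assert letters["orf20_NK-198-3"] == "c"

    def test_identical_replicates_get_distinct_letters(self):
        columns = {"a": (0.5, 0.5), "b": (0.3, 0.3), "c": (0.2, 0.2)}
        summary = summarize_replicates(_estimates_from_columns(columns))
        assert all(sd == 0.0 for sd in summary.sds.values())
        letters = set(summary.tukey_letters.values())
        assert len(letters) == 3

    def test_equal_means_with_large_variance_share_a_letter(self):
        columns = {
            "a": (0.70, 0.30, 0.50, 0.50),
            "b": (0.30, 0.70, 0.50, 0.50),
        }
        summary = summarize_replicates(_estimates_from_columns(columns))
        assert summary.tukey_letters["a"] == summary.tukey_letters["b"]

    def test_single_replicate_warns_and_omits_letters(self):
        est = _estimates_from_columns({"a": (0.6,), "b": (0.4,)})
        with pytest.warns(UserWarning, match="single replicate"):
            summary = summarize_replicates(est)
        assert summary.tukey_letters == {}
        assert summary.means == {"a": 0.6, "b": 0.4}
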