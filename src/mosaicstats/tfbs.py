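"""Context-adjusted mutation-rate statistics around active TFBS.

Builds genome-wide trinucleotide-context mutation rates, converts them into
expected counts for arbitrary region sets, and runs exact Poisson
observed/expected tests — including the annulus-differenced distance
profile around active-TFBS midpoints, the binned case/control rate profile,
the lower-tail binomial case-vs-control rate test, and a multi-track
O/E heatmap with Benjamini-Hochberg significance flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._contexts import (
    CONTEXT32_LABELS,
    SBS96_LABELS,
    census_contexts,
    classes_for,
    context32_of_channel,
    encode_seq,
)
from .intervals import IntervalTrack
from .reference import as_seq_dict
from .variants import Callset


@dataclass
class ActiveSiteConfig:
    """How 'active' TFBS are defined.

    ``dhs_quantile`` 0.90 matches the case/control profile convention
    (top decile of DHS intensity); genome-wide O/E analyses conventionally
    use 0.95 (top 5%).  Promoters are the 2.5 kb upstream of TSS.
    """

    dhs_quantile: float = 0.90
    promoter_window: int = 2500
    restrict_to_promoters: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.dhs_quantile < 1):
            raise ValueError("dhs_quantile must be in [0, 1)")


def active_tfbs(
    tfbs: IntervalTrack,
    dhs: IntervalTrack,
    config: ActiveSiteConfig | None = None,
    promoters: IntervalTrack | None = None,
) -> pd.DataFrame:
    """Midpoints of TFBS overlapping high-intensity DHS.

    The threshold is the empirical ``dhs_quantile`` of the DHS scores; a
    TFBS is active iff its interval overlaps a DHS interval with score at
    or above the threshold.  Midpoint = floor((start + end) / 2).  With
    ``restrict_to_promoters`` the midpoint must additionally fall in a
    promoter interval.
    """
    config = config or ActiveSiteConfig()
    if len(tfbs) == 0 or len(dhs) == 0:
        raise ValueError("no active TFBS: empty TFBS or DHS track")
    thr = np.quantile(dhs.scores, config.dhs_quantile)
    strong = dhs.frame[dhs.frame["score"] >= thr]
    strong_track = IntervalTrack("dhs_strong", strong[["chrom", "start", "end"]])

    frame = tfbs.frame
    keep = np.zeros(len(frame), dtype=bool)
    for i, row in enumerate(frame.itertuples(index=False)):
        sub = strong_track.frame[strong_track.frame["chrom"] == row.chrom]
        keep[i] = bool(((sub["start"] <= row.end) & (sub["end"] >= row.start)).any())
    active = frame[keep]
    mids = pd.DataFrame({
        "chrom": active["chrom"],
        "pos": (active["start"] + active["end"]) // 2,
    }).reset_index(drop=True)
    if config.restrict_to_promoters:
        if promoters is None:
            raise ValueError("restrict_to_promoters requires a promoter track")
        inside = promoters.contains(mids["chrom"].to_numpy(object),
                                    mids["pos"].to_numpy())
        mids = mids[inside].reset_index(drop=True)
    if len(mids) == 0:
        raise ValueError("no active TFBS survive the DHS threshold")
    return mids


# ---------------------------------------------------------------------------
# Context rates and expected counts
# ---------------------------------------------------------------------------

@dataclass
class ContextRateTable:
    """Genome-averaged per-site mutation rates by trinucleotide context.

    ``counts`` (length 96) are mutation counts per SBS channel;
    ``census`` (length 32) counts genomic sites per collapsed context; the
    per-channel rate divides each channel count by its context's census.
    """

    counts: np.ndarray
    census: np.ndarray
    scope: str = ""
    flagged_empty: bool = False

    @property
    def rates(self) -> np.ndarray:
        census_per_channel = self.census[[context32_of_channel(c) for c in range(96)]]
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(census_per_channel > 0, self.counts / census_per_channel, 0.0)
        return r

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "channel": SBS96_LABELS,
            "count": self.counts,
            "census": self.census[[context32_of_channel(c) for c in range(96)]],
            "rate": self.rates,
        })


def genome_context_rates(
    callset: Callset, reference, mask: np.ndarray | dict[str, np.ndarray] | None = None
) -> ContextRateTable:
    """Per-context mutation rates over the whole genome (or a masked subset).

    The census counts every interior genomic position once under the
    pyrimidine-collapsed 3-mer encoding; each annotated variant increments
    its SBS channel.  Rates are count / census.
    """
    seqs = as_seq_dict(reference)
    census = np.zeros(32, dtype=np.int64)
    for chrom, seq in seqs.items():
        m = mask[chrom] if isinstance(mask, dict) else mask
        census += census_contexts(encode_seq(seq), m)
    counts = np.zeros(96, dtype=np.int64)
    n = 0
    for records in callset.values():
        for r in records:
            if r.context_pyr is None:
                raise ValueError("callset must be context-annotated first")
            counts[r.sbs96] += 1
            n += 1
    return ContextRateTable(counts=counts, census=census,
                            scope=f"{len(callset)} samples, {n} mutations",
                            flagged_empty=(n == 0))


def region_census(region_mask: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Collapsed-context census (length 32) restricted to a boolean mask."""
    return census_contexts(codes, region_mask)


def expected_count(
    region_mask: np.ndarray | dict[str, np.ndarray],
    rates: ContextRateTable,
    reference,
    class_filter: str = "all",
) -> float:
    """Context-adjusted expected mutation count inside a region set.

    E = sum over the filtered SBS channels of (in-region context census x
    genome-wide channel rate).  The region is given as a per-base boolean
    mask (dict per contig or a single array for single-contig genomes).
    """
    seqs = as_seq_dict(reference)
    census = np.zeros(32, dtype=np.int64)
    for chrom, seq in seqs.items():
        m = region_mask[chrom] if isinstance(region_mask, dict) else region_mask
        census += census_contexts(encode_seq(seq), m)
    if census.sum() == 0:
        raise ValueError("region census is zero")
    channels = classes_for(class_filter)
    rate = rates.rates
    return float(sum(census[context32_of_channel(c)] * rate[c] for c in channels))


def observed_count(callset: Callset, in_region, class_filter: str = "all") -> int:
    """Count annotated variants inside a region mask, optionally by class.

    ``in_region`` is a callable ``(chrom, pos) -> bool`` or a boolean
    per-base mask (single contig).
    """
    channels = set(classes_for(class_filter).tolist())
    total = 0
    for records in callset.values():
        for r in records:
            if r.sbs96 not in channels:
                continue
            if callable(in_region):
                inside = in_region(r.chrom, r.pos)
            else:
                inside = bool(in_region[r.pos - 1])
            total += inside
    return total


# ---------------------------------------------------------------------------
# Exact Poisson O/E test
# ---------------------------------------------------------------------------

@dataclass
class OEResult:
    """Observed vs context-adjusted expected count with exact Poisson CI."""

    observed: int
    expected: float
    ratio: float
    ci_low: float
    ci_high: float
    p_one_sided: float
    p_two_sided: float
    label: str = ""
    class_filter: str = "all"


def oe_poisson_test(observed: int, expected: float, label: str = "",
                    class_filter: str = "all",
                    two_sided_method: str = "double_tail") -> OEResult:
    """Exact Poisson test of an observed count against an expected count.

    The 95% CI for the rate ratio uses the chi-square relationship
    (lower = qchisq(.025, 2O) / 2E, upper = qchisq(.975, 2O+2) / 2E).
    One-sided p = P(Poisson(E) >= O).  Two-sided p doubles the smaller
    tail by default; ``two_sided_method="minlike"`` sums all outcome
    probabilities <= the observed one instead.
    """
    if observed < 0 or expected <= 0:
        raise ValueError("need observed >= 0 and expected > 0")
    O, E = int(observed), float(expected)
    ratio = O / E
    lo = stats.chi2.ppf(0.025, 2 * O) / (2 * E) if O > 0 else 0.0
    hi = stats.chi2.ppf(0.975, 2 * O + 2) / (2 * E)
    upper = stats.poisson.sf(O - 1, E)  # P(X >= O)
    lower = stats.poisson.cdf(O, E)
    if two_sided_method == "double_tail":
        p2 = min(1.0, 2 * min(upper, lower))
    elif two_sided_method == "minlike":
        pmf_obs = stats.poisson.pmf(O, E)
        k = np.arange(0, max(int(E + 10 * np.sqrt(E) + 20), O + 1) + 1)
        pmf = stats.poisson.pmf(k, E)
        p2 = float(min(1.0, pmf[pmf <= pmf_obs * (1 + 1e-7)].sum()))
    else:
        raise ValueError(f"unknown two_sided_method {two_sided_method!r}")
    return OEResult(observed=O, expected=E, ratio=ratio, ci_low=float(lo),
                    ci_high=float(hi), p_one_sided=float(upper),
                    p_two_sided=float(p2), label=label, class_filter=class_filter)


# ---------------------------------------------------------------------------
# Distance machinery
# ---------------------------------------------------------------------------

def nearest_distance(pos: np.ndarray, mids: np.ndarray) -> np.ndarray:
    """Signed distance pos - nearest midpoint (ties to the earlier midpoint)."""
    mids = np.sort(np.asarray(mids, dtype=np.int64))
    pos = np.asarray(pos, dtype=np.int64)
    i = np.searchsorted(mids, pos)
    left = np.clip(i - 1, 0, len(mids) - 1)
    right = np.clip(i, 0, len(mids) - 1)
    d_left = pos - mids[left]
    d_right = pos - mids[right]
    take_left = np.abs(d_left) <= np.abs(d_right)
    return np.where(take_left, d_left, d_right)


def _genome_distances(L: int, mids: np.ndarray) -> np.ndarray:
    """Signed nearest-midpoint distance for every genomic position (1..L)."""
    return nearest_distance(np.arange(1, L + 1), mids)


@dataclass
class DistanceProfile:
    """Binned case/control rate profile around feature midpoints."""

    frame: pd.DataFrame  # per-bin rows
    pooled: pd.DataFrame  # pooled +/-1 kb comparison


def _poisson_rate_ratio(n1: int, n2: int, e1: float, e2: float):
    """Exact conditional two-group Poisson rate test with unequal exposure.

    Conditions on n1 + n2: n1 ~ Binomial(n, e1 / (e1 + e2)) under equal
    rates.  Returns (RR, lo, hi, p) with a Clopper-Pearson-derived CI.
    """
    n = n1 + n2
    pi0 = e1 / (e1 + e2)
    if n == 0:
        return np.nan, np.nan, np.nan, 1.0
    bt = stats.binomtest(n1, n, pi0)
    p = bt.pvalue
    ci = bt.proportion_ci(0.95)
    def rr_of(pi):
        if pi >= 1.0:
            return np.inf
        return (pi / (1 - pi)) * (e2 / e1)
    rr = (n1 / e1) / (n2 / e2) if n2 > 0 else np.inf
    return rr, rr_of(ci.low), rr_of(ci.high), float(p)


def rate_profile_case_control(
    case_callsets: Callset,
    control_callsets: Callset,
    midpoints: pd.DataFrame,
    reference,
    halfwidth: int = 10_000,
    binwidth: int = 2_000,
    pooled_halfwidth: int = 1_000,
) -> DistanceProfile:
    """Binned sSNV rate per Mb around midpoints, cases vs controls.

    Each mutation and each genomic site is assigned to its nearest midpoint
    (signed distance); per-bin opportunity = covered sites x genomes in the
    group, and the per-bin rate is scaled to events per Mb.  Each bin (and
    the pooled +/-``pooled_halfwidth`` window) gets an exact conditional
    Poisson rate-ratio test.
    """
    if not case_callsets or not control_callsets:
        raise ValueError("both groups must be non-empty")
    seqs = as_seq_dict(reference)
    (contig, seq), = seqs.items()
    mids = midpoints[midpoints["chrom"] == contig]["pos"].to_numpy()
    gdist = _genome_distances(len(seq), mids)

    edges = np.arange(-halfwidth, halfwidth + 1, binwidth)
    site_counts = np.histogram(gdist, bins=edges)[0]

    def _dists(callsets: Callset) -> np.ndarray:
        pos = np.array([r.pos for recs in callsets.values() for r in recs],
                       dtype=np.int64)
        return nearest_distance(pos, mids) if pos.size else pos

    d_case, d_ctrl = _dists(case_callsets), _dists(control_callsets)
    n_case, n_ctrl = len(case_callsets), len(control_callsets)
    c_case = np.histogram(d_case, bins=edges)[0]
    c_ctrl = np.histogram(d_ctrl, bins=edges)[0]

    rows = []
    for b in range(len(edges) - 1):
        opp_case = site_counts[b] * n_case
        opp_ctrl = site_counts[b] * n_ctrl
        if opp_case == 0 or opp_ctrl == 0:
            raise ValueError(f"bin {edges[b]}..{edges[b+1]} has zero opportunity")
        rr, lo, hi, p = _poisson_rate_ratio(
            int(c_case[b]), int(c_ctrl[b]), opp_case, opp_ctrl)
        rows.append({
            "bin_low": edges[b], "bin_high": edges[b + 1],
            "count_case": int(c_case[b]), "count_control": int(c_ctrl[b]),
            "opportunity_case": opp_case, "opportunity_control": opp_ctrl,
            "rate_case_per_mb": c_case[b] / opp_case * 1e6,
            "rate_control_per_mb": c_ctrl[b] / opp_ctrl * 1e6,
            "rate_ratio": rr, "ci_low": lo, "ci_high": hi, "p": p,
        })
    frame = pd.DataFrame(rows)

    in_core = np.abs(gdist) <= pooled_halfwidth
    core_sites = int(in_core.sum())
    n1 = int((np.abs(d_case) <= pooled_halfwidth).sum())
    n2 = int((np.abs(d_ctrl) <= pooled_halfwidth).sum())
    rr, lo, hi, p = _poisson_rate_ratio(
        n1, n2, core_sites * n_case, core_sites * n_ctrl)
    pooled = pd.DataFrame([{
        "halfwidth": pooled_halfwidth, "count_case": n1, "count_control": n2,
        "opportunity_case": core_sites * n_case,
        "opportunity_control": core_sites * n_ctrl,
        "rate_ratio": rr, "ci_low": lo, "ci_high": hi, "p": p,
    }])
    return DistanceProfile(frame=frame, pooled=pooled)


def annulus_oe_profile(
    callset: Callset,
    midpoints: pd.DataFrame,
    rates: ContextRateTable,
    reference,
    breaks=(50, 100, 500, 1000),
    class_filter: str = "all",
) -> list[OEResult]:
    """Observed/expected per disjoint annulus around midpoints.

    Nested windows [0, b] are differenced — both the observed counts and
    the context censuses — into annuli (b_{k-1}, b_k], so each annulus is
    statistically independent.  Overlapping windows from nearby midpoints
    are implicitly unioned because every site/mutation is scored by its
    nearest midpoint distance.
    """
    breaks = list(breaks)
    if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
        raise ValueError("breaks must be strictly increasing")
    seqs = as_seq_dict(reference)
    (contig, seq), = seqs.items()
    codes = encode_seq(seq)
    mids = midpoints[midpoints["chrom"] == contig]["pos"].to_numpy()
    gdist = np.abs(_genome_distances(len(seq), mids))

    channels = classes_for(class_filter)
    rate = rates.rates

    pos = np.array([r.pos for recs in callset.values() for r in recs
                    if r.sbs96 in set(channels.tolist())], dtype=np.int64)
    vdist = np.abs(nearest_distance(pos, mids)) if pos.size else pos

    results = []
    prev_O, prev_census = 0, np.zeros(32, dtype=np.int64)
    lo_edge = 0
    for b in breaks:
        O_cum = int((vdist <= b).sum())
        census_cum = census_contexts(codes, gdist <= b)
        O = O_cum - prev_O
        census = census_cum - prev_census
        E = float(sum(census[context32_of_channel(c)] * rate[c] for c in channels))
        label = f"({lo_edge},{b}]"
        if E <= 0:
            results.append(OEResult(observed=O, expected=0.0, ratio=np.nan,
                                    ci_low=np.nan, ci_high=np.nan,
                                    p_one_sided=np.nan, p_two_sided=np.nan,
                                    label=label, class_filter=class_filter))
        else:
            results.append(oe_poisson_test(O, E, label=label,
                                           class_filter=class_filter))
        prev_O, prev_census, lo_edge = O_cum, census_cum, b
    return results


# ---------------------------------------------------------------------------
# Case/control binomial rate test
# ---------------------------------------------------------------------------

@dataclass
class CaseControlRateTest:
    n1: int
    n2: int
    lambda1: float
    lambda2: float
    p_lower: float
    flagged: bool = False


def case_control_binomial(n1: int, n2: int, lambda1: float,
                          lambda2: float) -> CaseControlRateTest:
    """Lower-tail binomial test of the control share of mutations.

    With expected counts lambda1 (cases) and lambda2 (controls), under the
    null the n1 + n2 observed mutations split binomially with control
    probability lambda2 / (lambda1 + lambda2); the reported p is
    P(X <= n2) — small when controls carry fewer mutations than their
    expected share.
    """
    if lambda1 + lambda2 <= 0:
        raise ValueError("lambda1 + lambda2 must be positive")
    if n1 < 0 or n2 < 0:
        raise ValueError("counts must be non-negative")
    if n1 == 0 and n2 == 0:
        return CaseControlRateTest(n1, n2, lambda1, lambda2, 1.0, flagged=True)
    p = float(stats.binom.cdf(n2, n1 + n2, lambda2 / (lambda1 + lambda2)))
    return CaseControlRateTest(n1, n2, lambda1, lambda2, p)


# ---------------------------------------------------------------------------
# Multi-track heatmap
# ---------------------------------------------------------------------------

def multi_track_heatmap(
    callset: Callset,
    tfbs: IntervalTrack,
    dhs_tracks: dict[str, IntervalTrack],
    rates: ContextRateTable,
    reference,
    quantiles=(0.5, 0.75, 0.90, 0.95),
    window: int = 100,
    class_filter: str = "all",
    fdr: float = 0.05,
) -> pd.DataFrame:
    """O/E grid over (DHS track, activity quantile) with BH flags.

    Each cell defines active TFBS from its track/quantile, runs the exact
    Poisson O/E test on mutations within ``window`` bp of the midpoints,
    and the grid is Benjamini-Hochberg corrected across non-degenerate
    cells; ``significant`` marks adjusted p < ``fdr``.
    """
    seqs = as_seq_dict(reference)
    (contig, seq), = seqs.items()
    codes = encode_seq(seq)
    rows = []
    for tname, dhs in dhs_tracks.items():
        for q in quantiles:
            try:
                mids = active_tfbs(tfbs, dhs, ActiveSiteConfig(dhs_quantile=q))
            except ValueError:
                rows.append({"track": tname, "quantile": q, "observed": np.nan,
                             "expected": np.nan, "ratio": np.nan, "p": np.nan})
                continue
            marr = mids["pos"].to_numpy()
            gdist = np.abs(_genome_distances(len(seq), marr))
            census = census_contexts(codes, gdist <= window)
            channels = classes_for(class_filter)
            rate = rates.rates
            E = float(sum(census[context32_of_channel(c)] * rate[c]
                          for c in channels))
            chs = set(channels.tolist())
            pos = np.array([r.pos for recs in callset.values() for r in recs
                            if r.sbs96 in chs], dtype=np.int64)
            O = int((np.abs(nearest_distance(pos, marr)) <= window).sum()) if pos.size else 0
            if E <= 0:
                rows.append({"track": tname, "quantile": q, "observed": O,
                             "expected": np.nan, "ratio": np.nan, "p": np.nan})
                continue
            res = oe_poisson_test(O, E)
            rows.append({"track": tname, "quantile": q, "observed": O,
                         "expected": E, "ratio": res.ratio, "p": res.p_one_sided})
    grid = pd.DataFrame(rows)
    ok = grid["p"].notna()
    grid["p_adj"] = np.nan
    grid["significant"] = False
    if ok.any():
        rej, padj, _, _ = multipletests(grid.loc[ok, "p"], alpha=fdr, method="fdr_bh")
        grid.loc[ok, "p_adj"] = padj
        grid.loc[ok, "significant"] = rej
    return grid


def per_sample_oe(
    callset: Callset,
    midpoints: pd.DataFrame,
    rates_by_sample: dict[str, ContextRateTable],
    reference,
    window: int = 100,
    class_filter: str = "all",
) -> pd.DataFrame:
    """Per-sample O/E at active TFBS (the cancer-style enrichment scan).

    Expected counts use each sample's own genome-wide context rates so the
    ratio reflects localisation, not overall burden.
    """
    seqs = as_seq_dict(reference)
    (contig, seq), = seqs.items()
    codes = encode_seq(seq)
    marr = midpoints[midpoints["chrom"] == contig]["pos"].to_numpy()
    gdist = np.abs(_genome_distances(len(seq), marr))
    census = census_contexts(codes, gdist <= window)
    channels = classes_for(class_filter)
    chs = set(channels.tolist())
    rows = []
    for sid, records in callset.items():
        rate = rates_by_sample[sid].rates
        E = float(sum(census[context32_of_channel(c)] * rate[c] for c in channels))
        pos = np.array([r.pos for r in records if r.sbs96 in chs], dtype=np.int64)
        O = int((np.abs(nearest_distance(pos, marr)) <= window).sum()) if pos.size else 0
        ratio = O / E if E > 0 else np.nan
        rows.append({"sample_id": sid, "observed": O, "expected": E, "ratio": ratio})
    return pd.DataFrame(rows)
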