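"""Same-variant-same-site (SVSS) recurrence and hotspot-rate inference.

Recurrent identical somatic variants across unrelated samples are far more
likely under a bimodal (hotspot) mutation-rate model than under uniform
placement.  This module detects SVSS records, tests recurrence against a
Poisson collision null, derives the conservative lower bound on the
hotspot per-site rate (lambda1 >= 2 Nr / N_mut, with the genome average
lambda_bar = N_mut / n_sites), and profiles the conditional cross-sample
mutation density by distance, normalised in a far window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from ._contexts import classes_for
from .variants import Callset


@dataclass
class SVSSRecord:
    """The identical substitution at the identical position in >= 2 samples."""

    chrom: str
    pos: int
    ref: str
    alt: str
    carriers: list[str]
    vafs: list[float | None]


def find_svss(callsets: Callset, class_filter: str | None = None) -> list[SVSSRecord]:
    """Group variants by (chrom, pos, ref, alt); emit multi-sample groups.

    ``class_filter`` (e.g. ``"T>G"``) restricts to a substitution class;
    it requires annotated records when a context-specific filter is used,
    but plain substitutions are matched on ref/alt directly.  Duplicate
    records within one sample are deduplicated with a warning.  Output
    order is genomic, independent of input sample order.
    """
    if len(callsets) < 2:
        raise ValueError("need at least two samples")
    channels = None
    if class_filter is not None and len(class_filter) == 3 and class_filter[1] == ">":
        # plain substitution: match on collapsed ref>alt without annotation
        from ._contexts import COMPLEMENT
        ref, alt = class_filter[0].upper(), class_filter[2].upper()
        pairs = {(ref, alt), (COMPLEMENT[ref], COMPLEMENT[alt])}
    elif class_filter is not None:
        channels = set(classes_for(class_filter).tolist())
        pairs = None
    else:
        pairs = None

    groups: dict[tuple, dict[str, float | None]] = {}
    for sid, records in callsets.items():
        seen = set()
        for r in records:
            if pairs is not None and (r.ref, r.alt) not in pairs:
                continue
            if channels is not None and r.sbs96 not in channels:
                continue
            if r.key in seen:
                warnings.warn(f"duplicate record {r.key} in sample {sid}; deduplicated")
                continue
            seen.add(r.key)
            groups.setdefault(r.key, {})[sid] = r.vaf
    out = []
    for (chrom, pos, ref, alt), carriers in sorted(groups.items()):
        if len(carriers) >= 2:
            sids = sorted(carriers)
            out.append(SVSSRecord(chrom=chrom, pos=pos, ref=ref, alt=alt,
                                  carriers=sids, vafs=[carriers[s] for s in sids]))
    return out


@dataclass
class RecurrenceTest:
    """Poisson collision test for recurrent same-site mutations."""

    n_mut: int
    n_sites: float
    n_recurrent: int
    mu: float
    p_value: float


def recurrence_poisson_test(n_mut: int, n_sites: float,
                            n_recurrent: int) -> RecurrenceTest:
    """Upper-tail Poisson test of same-site pair collisions.

    Null: the ``n_mut`` mutations fall independently and uniformly over
    ``n_sites`` candidate sites, so the expected number of same-site pairs
    is mu = C(n_mut, 2) / n_sites (allele identity is automatic when the
    substitution class is fixed).  p = P(Poisson(mu) >= n_recurrent).
    """
    if n_mut < 2:
        raise ValueError("need at least two mutations")
    if n_sites < n_mut:
        raise ValueError("fewer candidate sites than mutations")
    mu = comb(n_mut, 2) / n_sites
    p = float(stats.poisson.sf(n_recurrent - 1, mu)) if n_recurrent > 0 else 1.0
    return RecurrenceTest(n_mut=n_mut, n_sites=n_sites,
                          n_recurrent=n_recurrent, mu=mu, p_value=p)


@dataclass
class HotspotModel:
    """Two-rate (hotspot / background) Poisson model, lower-bound form.

    From Nr observed recurrent sites among N_mut mutations of the class
    over n_sites candidate sites, dropping the (conservative) cross terms:

        lambda1 >= 2 Nr / N_mut,    lambda_bar = N_mut / n_sites,
        fold = lambda1_bound / lambda_bar = 2 Nr n_sites / N_mut^2.
    """

    n_recurrent: int
    n_mut: int
    n_sites: float
    flagged: bool = False

    @classmethod
    def from_recurrence(cls, n_recurrent: int, n_mut: int,
                        n_sites: float) -> "HotspotModel":
        if n_mut <= 0 or n_sites <= 0:
            raise ValueError("n_mut and n_sites must be positive")
        flagged = n_recurrent > n_mut / 2
        if flagged:
            warnings.warn("Nr > N_mut/2: two-rate model assumptions violated")
        return cls(n_recurrent=n_recurrent, n_mut=n_mut, n_sites=n_sites,
                   flagged=flagged)

    @property
    def lambda1_bound(self) -> float:
        return 2 * self.n_recurrent / self.n_mut

    @property
    def lambda_bar(self) -> float:
        return self.n_mut / self.n_sites

    @property
    def fold(self) -> float:
        return self.lambda1_bound / self.lambda_bar

    def summary(self) -> str:
        return "\n".join([
            "Hotspot two-rate model (lower bound)",
            "=" * 40,
            f"recurrent sites Nr   : {self.n_recurrent}",
            f"class mutations N_mut: {self.n_mut}",
            f"candidate sites      : {self.n_sites:.4g}",
            f"lambda1 lower bound  : {self.lambda1_bound:.4g}",
            f"genome average rate  : {self.lambda_bar:.4g}",
            f"hotspot fold         : {self.fold:.4g}",
        ])


def hotspot_rate_bound(n_recurrent: int, n_mut: int, n_sites: float) -> HotspotModel:
    """Functional wrapper for :meth:`HotspotModel.from_recurrence`."""
    return HotspotModel.from_recurrence(n_recurrent, n_mut, n_sites)


# ---------------------------------------------------------------------------
# Conditional recurrence density
# ---------------------------------------------------------------------------

@dataclass
class RecurrenceProfile:
    """Cross-sample mutation density by distance from a focal mutation."""

    distances: np.ndarray
    density: np.ndarray
    normalized: np.ndarray
    norm_constant: float
    n_opportunities: int
    flagged: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"distance": self.distances, "density": self.density,
                             "normalized": self.normalized})


def conditional_recurrence_density(
    callsets: Callset, max_dist: int = 100, norm_bins: tuple[int, int] = (91, 100)
) -> RecurrenceProfile:
    """Density of mutations at each distance from a focal mutation in
    another sample.

    For every ordered pair of distinct samples and every focal mutation in
    the first, mutations in the second are tallied by absolute distance
    0..``max_dist`` (0 = same position; allele identity is not required).
    Density divides the tally by the number of (ordered pair, focal)
    opportunities; normalised density divides by the mean over
    ``norm_bins`` (inclusive), so that window averages exactly 1.
    """
    if len(callsets) < 2:
        raise ValueError("need at least two samples")
    by_sample = {
        sid: {chrom: np.sort(np.array([r.pos for r in records if r.chrom == chrom]))
              for chrom in {r.chrom for r in records}}
        for sid, records in callsets.items()
    }
    tally = np.zeros(max_dist + 1, dtype=np.int64)
    n_opp = 0
    sids = list(by_sample)
    for a in sids:
        for b in sids:
            if a == b:
                continue
            for chrom, pos_a in by_sample[a].items():
                n_opp += pos_a.size
                pos_b = by_sample[b].get(chrom)
                if pos_b is None or pos_b.size == 0:
                    continue
                d = np.abs(pos_a[:, None] - pos_b[None, :])
                close = d[d <= max_dist]
                tally += np.bincount(close, minlength=max_dist + 1)
    if n_opp == 0:
        raise ValueError("no focal mutations")
    density = tally / n_opp
    lo, hi = norm_bins
    if hi > max_dist:
        raise ValueError("normalisation window exceeds max_dist")
    norm = float(density[lo: hi + 1].mean())
    flagged = norm == 0
    if flagged:
        warnings.warn("zero density in the normalisation window")
        normalized = np.full_like(density, np.nan)
    else:
        normalized = density / norm
    return RecurrenceProfile(distances=np.arange(max_dist + 1), density=density,
                             normalized=normalized, norm_constant=norm,
                             n_opportunities=n_opp, flagged=flagged)


# ---------------------------------------------------------------------------
# Carrier stratification
# ---------------------------------------------------------------------------

@dataclass
class RankSumResult:
    statistic: float
    p_value: float
    n_carriers: int
    n_noncarriers: int
    method: str


def carrier_stratified_oe(per_sample_ratios: dict[str, float],
                          carrier_labels: dict[str, bool]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum on per-sample O/E between carrier strata.

    The exact null distribution is used for groups of <= 25 without ties;
    otherwise the tie-corrected normal approximation.
    """
    carriers = [v for s, v in per_sample_ratios.items() if carrier_labels.get(s)]
    noncarriers = [v for s, v in per_sample_ratios.items() if not carrier_labels.get(s)]
    if len(carriers) < 2 or len(noncarriers) < 2:
        raise ValueError("need at least two samples per stratum")
    has_ties = len(set(carriers + noncarriers)) < len(carriers) + len(noncarriers)
    exact = max(len(carriers), len(noncarriers)) <= 25 and not has_ties
    res = stats.mannwhitneyu(carriers, noncarriers, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return RankSumResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                         n_carriers=len(carriers), n_noncarriers=len(noncarriers),
                         method="exact" if exact else "normal_approx")
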