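"""The rarefaction engine.

Occurrence counts differ wildly between intervals and regions, so raw
richness is not comparable across strata.  Classical rarefaction standardises
sampling effort: every stratum in a comparison is repeatedly subsampled
WITHOUT replacement to a shared quota — 80% of the smallest stratum's
occurrence count by default — and richness is summarised over replicates
(median, quartiles, Tukey whiskers).

Replicate ``r`` of stratum ``s`` is reproducible in isolation: its random
stream is derived from (plan seed, stratum index, r), so a full run, a
re-run, and a single-replicate audit all see identical draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .incidence import Stratum
from .io import EVALUABILITY_FLOOR

DEFAULT_FRACTION = 0.80
DEFAULT_REPLICATES = 10_000


@dataclass
class RarefactionPlan:
    """A shared-quota subsampling design over an ordered list of strata."""

    strata: list[Stratum]
    fraction: float
    quota: int
    replicates: int
    seed: int


@dataclass
class RarefiedDistribution:
    """Replicate richness values for one stratum under a plan's quota."""

    stratum_key: object
    replicate_richness: np.ndarray
    median: float = field(init=False)
    q1: float = field(init=False)
    q3: float = field(init=False)
    whisker_low: float = field(init=False)
    whisker_high: float = field(init=False)

    def __post_init__(self) -> None:
        self.replicate_richness = np.asarray(self.replicate_richness)
        s = summarize(self.replicate_richness)
        self.median, self.q1, self.q3 = s["median"], s["q1"], s["q3"]
        self.whisker_low, self.whisker_high = s["whisker_low"], s["whisker_high"]


def make_plan(
    strata: Sequence[Stratum],
    fraction: float = DEFAULT_FRACTION,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    floor: int | None = EVALUABILITY_FLOOR,
) -> RarefactionPlan:
    """Build a plan with quota = floor(fraction × smallest stratum size).

    All strata being compared share the one quota.  By default every stratum
    must clear the 15-occurrence evaluability floor; pass ``floor=None`` to
    override explicitly (the caller then owns the interpretability caveat).
    """
    strata = list(strata)
    if not strata:
        raise ValueError("plan needs at least one stratum")
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    for s in strata:
        if s.is_empty:
            raise ValueError(f"empty stratum {s.key.label()}")
        if floor is not None and s.n_occurrences < floor:
            raise ValueError(
                f"stratum {s.key.label()} has {s.n_occurrences} occurrences, "
                f"below the evaluability floor of {floor}"
            )
    quota = int(np.floor(fraction * min(s.n_occurrences for s in strata)))
    if quota < 1:
        raise ValueError("quota is 0; strata too small for this fraction")
    return RarefactionPlan(strata, fraction, quota, int(replicates), int(seed))


def replicate_rng(seed: int, stratum_index: int, replicate: int) -> np.random.Generator:
    """The generator for one (stratum, replicate) cell of a plan."""
    ss = np.random.SeedSequence(
        entropy=(int(seed), int(stratum_index)), spawn_key=(int(replicate),)
    )
    return np.random.default_rng(ss)


def _encode(stratum: Stratum, vocabulary: np.ndarray | None = None):
    """Map the stratum's occurrence taxa to integer codes."""
    if vocabulary is None:
        vocabulary, codes = np.unique(stratum.taxa.astype(str), return_inverse=True)
        return vocabulary, codes
    codes = np.searchsorted(vocabulary, stratum.taxa.astype(str))
    return vocabulary, codes


def subsample_codes(
    codes: np.ndarray, quota: int, rng: np.random.Generator
) -> np.ndarray:
    """One subsample of ``quota`` occurrences drawn without replacement."""
    n = codes.size
    if quota > n:
        raise ValueError(f"quota {quota} exceeds stratum size {n}")
    idx = rng.choice(n, size=quota, replace=False)
    return codes[idx]


def rarefy_richness(plan: RarefactionPlan) -> list[RarefiedDistribution]:
    """Replicate subsampled richness for every stratum of the plan."""
    out = []
    for s_index, stratum in enumerate(plan.strata):
        _, codes = _encode(stratum)
        n_taxa = int(codes.max()) + 1 if codes.size else 0
        richness = np.empty(plan.replicates, dtype=np.int64)
        for r in range(plan.replicates):
            rng = replicate_rng(plan.seed, s_index, r)
            sub = subsample_codes(codes, plan.quota, rng)
            richness[r] = np.count_nonzero(np.bincount(sub, minlength=n_taxa))
        out.append(RarefiedDistribution(stratum.key, richness))
    return out


def summarize(values: np.ndarray) -> dict:
    """Median, quartiles and Tukey whiskers of a replicate distribution.

    Quartiles use linear interpolation between order statistics; whiskers are
    the quartiles ± 1.5 × IQR, clipped to the most extreme observed values
    inside the fences (the usual box-plot convention).
    """
    values = np.asarray(values)
    if values.size == 0:
        raise ValueError("empty replicate list")
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(values[values >= lo_fence].min()),
        "whisker_high": float(values[values <= hi_fence].max()),
    }


def percent_change(median_a: float, median_b: float) -> float:
    """Signed percent change from a baseline median to a later one.

    ``percent_change(100, 50) == -50.0``.  Undefined for a zero/negative
    baseline.
    """
    if median_a <= 0:
        raise ValueError("percent change undefined for baseline <= 0")
    return (median_b - median_a) / median_a * 100.0


def expected_richness(taxon_counts: Sequence[int], quota: int) -> float:
    """Exact expected subsampled richness under the hypergeometric model.

    For occurrence counts n_i summing to N, the expected number of taxa in a
    without-replacement subsample of size q is
    ``sum_i 1 - C(N - n_i, q)/C(N, q)`` — i.e. one minus the probability the
    taxon is missed entirely.  This closed form is the analytic check for the
    Monte-Carlo engine.
    """
    counts = np.asarray(list(taxon_counts), dtype=np.int64)
    n_total = int(counts.sum())
    if not (0 < quota <= n_total):
        raise ValueError("quota must be in 1..total occurrences")
    p_missing = hypergeom.pmf(0, n_total, counts, quota)
    return float(np.sum(1.0 - p_missing))


def distribution_table(dists: Sequence[RarefiedDistribution]) -> pd.DataFrame:
    rows = []
    for d in dists:
        k = d.stratum_key
        rows.append(
            {
                "group": k.group,
                "interval": k.interval,
                "region": k.region or "all",
                "coral_ecology": k.coral_ecology or "all",
                "replicates": int(d.replicate_richness.size),
                "median": d.median,
                "q1": d.q1,
                "q3": d.q3,
                "whisker_low": d.whisker_low,
                "whisker_high": d.whisker_high,
            }
        )
    return pd.DataFrame(rows)
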