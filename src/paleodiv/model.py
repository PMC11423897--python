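"""Model/Results interface over the occurrence-diversity pipeline.

:class:`DiversityAnalysis` is constructed from a validated occurrence
dataset (or a CSV path, DataFrame, or synthetic scenario) together with the
analysis configuration — taxonomic level, spatial scope, rarefaction
fraction and replicate count, evaluability floor.  ``fit(seed)`` runs the
whole pipeline deterministically and returns a :class:`DiversityResults`
carrying the rarefied richness panel (median, quartiles, whiskers, percent
change against the oldest-interval baseline), the exact and rarefied beta
partitions for every interval pair, the rank-test table, and writers/plots.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .beta import PAIRS_DEFAULT, partition_exact, partition_rarefied
from .incidence import build_stratum
from .inference import rank_sum_test, signed_rank_test
from .io import (
    EVALUABILITY_FLOOR,
    INTERVALS,
    INTERVAL_LABELS,
    NOT_ANALYZED_GROUPS,
    REGIONS,
    OccurrenceDataset,
    check_evaluability,
    read_occurrences,
    validate_frame,
)
from .resampling import (
    DEFAULT_FRACTION,
    DEFAULT_REPLICATES,
    make_plan,
    percent_change,
    rarefy_richness,
)

_PAIR_LABEL = {
    (a, b): f"{INTERVAL_LABELS[a]}–{INTERVAL_LABELS[b]}" for a, b in PAIRS_DEFAULT
}


def _subseed(seed: int, *key) -> int:
    """Stable sub-stream seed (< 2^31) for one unit of work."""
    ss = np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


class DiversityAnalysis:
    """Rarefied richness and beta-diversity model of an occurrence dataset.

    Parameters
    ----------
    dataset : OccurrenceDataset
        Validated occurrences; reworked records are dropped here.
    groups : sequence of str, optional
        Groups to analyse.  Defaults to every group present except those
        recorded too sparsely for per-group statistics (sharks, marine
        mammals), which require ``include_unanalyzed=True``.
    level : {'species', 'genus'}
        Taxonomic level; genus level re-deduplicates after aggregation.
    scope : {'mediterranean', 'regional'}
        Whole-basin strata, or one analysis per region.
    fraction, replicates : float, int
        Rarefaction: subsample to ``floor(fraction × smallest n)`` with this
        many replicates (defaults 0.80 and 10,000).
    comparison : {'three_way', 'pairwise'}
        Quota scope for the richness panel: one quota shared by all three
        intervals (default, box-plot style) or one per interval pair.  Beta
        partitions always use the pair's own quota.
    coral_ecology : {'all', 'z', 'az'}
        Ecology slice applied to the corals group.
    """

    def __init__(
        self,
        dataset: OccurrenceDataset,
        *,
        groups: Sequence[str] | None = None,
        level: str = "species",
        scope: str = "mediterranean",
        fraction: float = DEFAULT_FRACTION,
        replicates: int = DEFAULT_REPLICATES,
        comparison: str = "three_way",
        floor: int = EVALUABILITY_FLOOR,
        include_unanalyzed: bool = False,
        coral_ecology: str = "all",
    ):
        if level not in ("species", "genus"):
            raise ValueError(f"unknown level {level!r}")
        if scope not in ("mediterranean", "regional"):
            raise ValueError(f"unknown scope {scope!r}")
        if comparison not in ("three_way", "pairwise"):
            raise ValueError(f"unknown comparison scope {comparison!r}")
        if not (0 < fraction <= 1):
            raise ValueError("fraction must be in (0, 1]")
        if replicates < 1:
            raise ValueError("replicates must be >= 1")

        self.dataset = dataset
        ds = dataset.filter_reworked()
        if level == "genus":
            ds = ds.aggregate_to_genus()
        self._ds = ds

        present = list(dict.fromkeys(ds.frame["group"]))
        if groups is None:
            groups = [g for g in present if g not in NOT_ANALYZED_GROUPS]
            if include_unanalyzed:
                groups = present
        self.groups = list(groups)
        self.level = level
        self.scope = scope
        self.fraction = float(fraction)
        self.replicates = int(replicates)
        self.comparison = comparison
        self.floor = int(floor)
        self.include_unanalyzed = include_unanalyzed
        self.coral_ecology = coral_ecology

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_csv(
        cls,
        path,
        column_map: Mapping[str, str] | None = None,
        sep: str | None = None,
        **kwargs,
    ) -> "DiversityAnalysis":
        return cls(read_occurrences(path, column_map=column_map, sep=sep), **kwargs)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, **kwargs) -> "DiversityAnalysis":
        return cls(validate_frame(frame.astype(str)), **kwargs)

    @classmethod
    def from_scenario(cls, spec, **kwargs) -> "DiversityAnalysis":
        """Build from a synthetic :class:`~paleodiv.synthetic.ScenarioSpec`."""
        from .synthetic import generate

        ds, truth = generate(spec)
        model = cls(ds, **kwargs)
        model.ground_truth = truth
        return model

    # -- fitting ------------------------------------------------------------

    @property
    def config(self) -> dict:
        return {
            "groups": self.groups,
            "level": self.level,
            "scope": self.scope,
            "fraction": self.fraction,
            "replicates": self.replicates,
            "comparison": self.comparison,
            "floor": self.floor,
            "coral_ecology": self.coral_ecology,
        }

    def _units(self):
        regions = [None] if self.scope == "mediterranean" else list(REGIONS)
        for gi, group in enumerate(self.groups):
            for ri, region in enumerate(regions):
                yield gi, ri, group, region

    def fit(self, seed: int = 0) -> "DiversityResults":
        """Run rarefaction, beta partitioning and rank tests; deterministic."""
        richness_rows: list[dict] = []
        beta_rows: list[dict] = []
        beta_exact_rows: list[dict] = []
        test_rows: list[dict] = []

        for gi, ri, group, region in self._units():
            eco = self.coral_ecology if group == "corals" else None
            eco = None if eco == "all" else eco
            strata = {
                iv: build_stratum(self._ds, group, iv, region=region, coral_ecology=eco)
                for iv in INTERVALS
            }
            evaluable = {
                iv: s.n_occurrences >= self.floor for iv, s in strata.items()
            }
            base = {
                "group": group,
                "region": region or "all",
                "coral_ecology": eco or "all",
            }

            richness_rows.extend(
                self._richness_panel(strata, evaluable, base, seed, gi, ri)
            )

            for pi, (iv_a, iv_b) in enumerate(PAIRS_DEFAULT):
                sa, sb = strata[iv_a], strata[iv_b]
                row = dict(
                    base,
                    pair=_PAIR_LABEL[(iv_a, iv_b)],
                    n_a=sa.n_occurrences,
                    n_b=sb.n_occurrences,
                    quota=np.nan,
                    replicates=self.replicates,
                    a=np.nan, b=np.nan, c=np.nan,
                    beta_sor=np.nan, beta_sim=np.nan, beta_nes=np.nan,
                    status="ok",
                )
                xrow = {
                    k: row[k]
                    for k in ("group", "region", "coral_ecology", "pair", "n_a", "n_b")
                }
                xrow.update(
                    beta_sor=np.nan, beta_sim=np.nan, beta_nes=np.nan, status="ok"
                )
                low = [iv for iv in (iv_a, iv_b) if not evaluable[iv]]
                if low:
                    msg = "non-evaluable: " + ", ".join(
                        f"{iv} (n={strata[iv].n_occurrences})" for iv in low
                    )
                    row["status"] = xrow["status"] = msg
                    beta_rows.append(row)
                    beta_exact_rows.append(xrow)
                    test_rows.extend(
                        self._test_rows(base, _PAIR_LABEL[(iv_a, iv_b)], None, msg)
                    )
                    continue

                xpart = partition_exact(sa.assemblage, sb.assemblage)
                xrow.update(
                    beta_sor=xpart.beta_sor,
                    beta_sim=xpart.beta_sim,
                    beta_nes=xpart.beta_nes,
                )
                beta_exact_rows.append(xrow)

                part, reps = partition_rarefied(
                    sa,
                    sb,
                    fraction=self.fraction,
                    replicates=self.replicates,
                    seed=_subseed(seed, 1, gi, ri, pi),
                    floor=self.floor,
                )
                row.update(
                    quota=part.meta["quota"],
                    a=part.a_shared, b=part.b_only, c=part.c_only,
                    beta_sor=part.beta_sor,
                    beta_sim=part.beta_sim,
                    beta_nes=part.beta_nes,
                )
                beta_rows.append(row)
                test_rows.extend(
                    self._test_rows(base, _PAIR_LABEL[(iv_a, iv_b)], reps, "ok")
                )

        return DiversityResults(
            model=self,
            seed=int(seed),
            richness_=pd.DataFrame(richness_rows),
            beta_=pd.DataFrame(beta_rows),
            beta_exact_=pd.DataFrame(beta_exact_rows),
            tests_=pd.DataFrame(test_rows),
            evaluability_=check_evaluability(
                self._ds, groups=self.groups, floor=self.floor
            ),
        )

    # -- pieces -------------------------------------------------------------

    def _richness_panel(self, strata, evaluable, base, seed, gi, ri) -> list[dict]:
        """Box-plot statistics per interval plus percent change vs baseline."""
        rows = []
        usable = [iv for iv in INTERVALS if evaluable[iv]]
        dists: dict[str, object] = {}
        quota = np.nan
        if self.comparison == "three_way":
            if usable:
                plan = make_plan(
                    [strata[iv] for iv in usable],
                    self.fraction,
                    self.replicates,
                    seed=_subseed(seed, 0, gi, ri),
                    floor=self.floor,
                )
                quota = plan.quota
                dists = dict(zip(usable, rarefy_richness(plan)))
        else:  # pairwise: each interval rarefied under every pair quota it joins
            for pi, (iv_a, iv_b) in enumerate(PAIRS_DEFAULT):
                if evaluable[iv_a] and evaluable[iv_b]:
                    plan = make_plan(
                        [strata[iv_a], strata[iv_b]],
                        self.fraction,
                        self.replicates,
                        seed=_subseed(seed, 0, gi, ri, pi),
                        floor=self.floor,
                    )
                    for iv, d in zip((iv_a, iv_b), rarefy_richness(plan)):
                        rows.append(
                            self._richness_row(
                                base, iv, strata[iv], d, plan.quota,
                                pair=_PAIR_LABEL[(iv_a, iv_b)],
                            )
                        )
            return rows

        medians = {}
        for iv in INTERVALS:
            s = strata[iv]
            d = dists.get(iv)
            row = self._richness_row(base, iv, s, d, quota, pair="")
            if d is not None:
                medians[iv] = d.median
            rows.append(row)

        t0 = medians.get("tortonian")
        prev = {"messinian_pre_evaporitic": "tortonian", "zanclean": "messinian_pre_evaporitic"}
        for row in rows:
            iv = row["interval"]
            if iv in medians and t0 and iv != "tortonian":
                row["pct_vs_tortonian"] = percent_change(t0, medians[iv])
            p = prev.get(iv)
            if iv in medians and p in medians and medians[p] > 0:
                row["pct_vs_previous"] = percent_change(medians[p], medians[iv])
        return rows

    def _richness_row(self, base, interval, stratum, dist, quota, pair) -> dict:
        row = dict(
            base,
            interval=interval,
            pair=pair,
            n_occurrences=stratum.n_occurrences,
            richness_raw=stratum.richness_raw,
            quota=quota if dist is not None else np.nan,
            replicates=self.replicates if dist is not None else 0,
            median=np.nan, q1=np.nan, q3=np.nan,
            whisker_low=np.nan, whisker_high=np.nan,
            pct_vs_tortonian=np.nan,
            pct_vs_previous=np.nan,
            status="ok",
        )
        if dist is None:
            row["status"] = (
                "no data"
                if stratum.n_occurrences == 0
                else f"non-evaluable (n={stratum.n_occurrences} < {self.floor})"
            )
        else:
            row.update(
                median=dist.median, q1=dist.q1, q3=dist.q3,
                whisker_low=dist.whisker_low, whisker_high=dist.whisker_high,
            )
        return row

    def _test_rows(self, base, pair_label, reps, status) -> list[dict]:
        rows = []
        for variant in ("two_sample_rank_sum", "one_sample_signed_rank"):
            row = dict(
                base,
                pair=pair_label,
                test=variant,
                alternative="",
                statistic=np.nan,
                p_value=np.nan,
                n1=0,
                n2=0,
                method="",
                caveat="",
                status=status,
            )
            if reps is not None:
                ra = reps["richness_a"].to_numpy()
                rb = reps["richness_b"].to_numpy()
                d = rb - ra
                alt = "less" if np.median(d) < 0 else "greater"
                try:
                    if variant == "two_sample_rank_sum":
                        tr = rank_sum_test(rb, ra, alternative=alt)
                    else:
                        tr = signed_rank_test(d, alternative=alt)
                    row.update(
                        alternative=tr.alternative,
                        statistic=tr.statistic,
                        p_value=tr.p_value,
                        n1=tr.n1,
                        n2=tr.n2,
                        method=tr.method,
                        caveat=tr.caveat,
                    )
                except ValueError as exc:  # degenerate distributions
                    row["status"] = f"degenerate: {exc}"
            rows.append(row)
        return rows


@dataclass
class DiversityResults:
    """Fitted tables plus summary, writers and plots."""

    model: DiversityAnalysis
    seed: int
    richness_: pd.DataFrame
    beta_: pd.DataFrame
    beta_exact_: pd.DataFrame
    tests_: pd.DataFrame
    evaluability_: pd.DataFrame

    # -- derived ------------------------------------------------------------

    @property
    def n_evaluable_comparisons(self) -> int:
        if self.beta_.empty:
            return 0
        return int((self.beta_["status"] == "ok").sum())

    def percent_change_table(self) -> pd.DataFrame:
        """Median richness per interval, normalised to the oldest interval."""
        df = self.richness_[self.richness_["status"] == "ok"]
        out = df.loc[
            :, ["group", "region", "interval", "median",
                "pct_vs_tortonian", "pct_vs_previous"]
        ].copy()
        return out.reset_index(drop=True)

    # -- presentation --------------------------------------------------------

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Occurrence-based diversity analysis",
            "=" * 72,
            f"level: {cfg['level']}   scope: {cfg['scope']}   "
            f"fraction: {cfg['fraction']}   replicates: {cfg['replicates']}   "
            f"seed: {self.seed}",
            f"groups: {', '.join(cfg['groups'])}",
            f"evaluability floor: {cfg['floor']} occurrences "
            f"({int(self.evaluability_['evaluable'].sum())}/"
            f"{len(self.evaluability_)} strata evaluable)",
            "",
            "Rarefied richness (median and box statistics per interval)",
            "-" * 72,
            self.richness_.to_string(
                index=False, float_format=lambda v: f"{v:.1f}"
            ),
            "",
            "Beta partition, rarefied medians (total = Sørensen, turnover = "
            "Simpson, nestedness = remainder)",
            "-" * 72,
            self.beta_.drop(columns=["replicates"]).to_string(
                index=False, float_format=lambda v: f"{v:.3f}"
            ),
            "",
            "Rank tests on replicate richness (one-tailed; replicate p-values "
            "are pseudo-replicate artifacts — see caveat column in tests.csv)",
            "-" * 72,
            self.tests_.drop(columns=["caveat"]).to_string(
                index=False, float_format=lambda v: f"{v:.3g}"
            ),
            "",
        ]
        return "\n".join(lines)

    # -- output --------------------------------------------------------------

    def to_output_dir(self, outdir) -> dict:
        """Write every result table plus a provenance manifest; returns paths.

        Output is byte-deterministic for a fixed dataset, configuration and
        seed (fixed column order, fixed float format, no timestamps).
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tables = {
            "richness.csv": self.richness_,
            "beta.csv": self.beta_,
            "beta_exact.csv": self.beta_exact_,
            "tests.csv": self.tests_,
            "evaluability.csv": self.evaluability_,
        }
        files = {}
        for name, df in tables.items():
            path = outdir / name
            df.to_csv(path, index=False, float_format="%.10g")
            files[name] = _sha256(path)
        (outdir / "summary.txt").write_text(self.summary())
        files["summary.txt"] = _sha256(outdir / "summary.txt")
        manifest = {
            "package": "paleodiv",
            "version": __version__,
            "seed": self.seed,
            "config": self.model.config,
            "source": self.model.dataset.source_label,
            "n_occurrences": len(self.model.dataset),
            "files": files,
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
        return {name: outdir / name for name in list(files) + ["manifest.json"]}

    # -- plots ---------------------------------------------------------------

    def plot_richness(self, region: str = "all", ax=None):
        """Box-style richness panel per group × interval (precomputed stats)."""
        import matplotlib.pyplot as plt

        df = self.richness_[
            (self.richness_["status"] == "ok")
            & (self.richness_["region"] == region)
        ]
        groups = list(dict.fromkeys(df["group"]))
        if ax is None:
            _, ax = plt.subplots(figsize=(max(6, 1.2 * 3 * len(groups)), 4))
        boxes, positions, labels = [], [], []
        pos = 0
        for g in groups:
            sub = df[df["group"] == g]
            for _, r in sub.iterrows():
                boxes.append(
                    {
                        "med": r["median"],
                        "q1": r["q1"],
                        "q3": r["q3"],
                        "whislo": r["whisker_low"],
                        "whishi": r["whisker_high"],
                        "fliers": [],
                    }
                )
                positions.append(pos)
                labels.append(f"{g[:12]}\n{INTERVAL_LABELS[r['interval']]}")
                pos += 1
            pos += 1
        ax.bxp(boxes, positions=positions, showfliers=False)
        ax.set_xticks(positions)
        ax.set_xticklabels(labels, fontsize=7)
        ax.set_ylabel("rarefied richness")
        return ax

    def plot_beta(self, region: str = "all", ax=None):
        """Grouped bars of total dissimilarity, turnover and nestedness."""
        import matplotlib.pyplot as plt

        df = self.beta_[
            (self.beta_["status"] == "ok") & (self.beta_["region"] == region)
        ]
        if ax is None:
            _, ax = plt.subplots(figsize=(max(6, 0.6 * len(df)), 4))
        x = np.arange(len(df))
        w = 0.27
        ax.bar(x - w, df["beta_sor"], w, color="black", label="total (Sørensen)")
        ax.bar(x, df["beta_sim"], w, color="tab:red", label="turnover (Simpson)")
        ax.bar(x + w, df["beta_nes"], w, color="tab:blue", label="nestedness")
        ax.set_xticks(x)
        ax.set_xticklabels(
            df["group"].str[:10] + " " + df["pair"], rotation=90, fontsize=7
        )
        ax.set_ylabel("dissimilarity")
        ax.legend(fontsize=8)
        return ax


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()
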