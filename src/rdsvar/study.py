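"""Replicated RDS simulation studies and their aggregate diagnostics.

:func:`run_study` draws repeated branching RDS samples from a known network,
applies the requested variance estimators to each, and aggregates:

* population sampling variance — mean squared deviation of the replicate
  point estimates around the true mean (an MSE around truth, not a central
  variance);
* per-method bias (mean estimated variance minus population variance),
  ratio (mean estimated variance over population variance), 95% coverage,
  and empirical/estimated design effects;
* a panel split of replicates by the sample-level FOM verdict, to ask
  whether a rejecting sample signals worse variance estimation.

Across networks, :func:`cross_network_correlation` correlates mean estimated
variances with population variances, and :func:`bias_homophily_regression`
runs the XY-standardized regression of per-sample bias on sample-level
homophily, optionally absorbing network fixed effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .estimators import coverage_hit, sbe_variance, vhe_variance
from .fomtest import fom_test
from .graphs import Network
from .sampler import (
    DEFAULT_BRANCH_PROBS,
    RecruitmentForest,
    empirical_sampling_variance,
    rds_sample,
)

__all__ = [
    "StudyResult",
    "run_study",
    "homophily_ratio",
    "bias_homophily_regression",
    "cross_network_correlation",
    "METHODS",
]

METHODS: dict[str, Callable[..., object]] = {
    "vhe": lambda f: vhe_variance(f, distance_mode="sequence", order=1),
    "vhewbc": lambda f: vhe_variance(f, distance_mode="tree", order=1),
    "vhehom2": lambda f: vhe_variance(f, distance_mode="tree", order=2),
    "vhehom3": lambda f: vhe_variance(f, distance_mode="tree", order=3),
}


@dataclass
class StudyResult:
    """Per-replicate estimates plus the aggregate diagnostics of one network."""

    network_id: str
    s: int
    r: int
    mu: float
    per_replicate: pd.DataFrame
    population_sampling_variance: float
    aggregates: pd.DataFrame  # one row per method: bias, ratio, coverage, DEs
    panels: pd.DataFrame  # same statistics split by sample FOM verdict

    @property
    def empirical_design_effect(self) -> float:
        srs = self.mu * (1 - self.mu) / self.s
        return self.population_sampling_variance / srs if srs > 0 else float("nan")


def homophily_ratio(forest: RecruitmentForest) -> float:
    """Observed over expected cross-group referral ties in one sample.

    Expected cross ties under proportionate mixing are T * 2 phat (1 - phat)
    with phat the sample proportion.  Undefined (NaN) for single-category
    samples or samples without referrals.
    """
    pairs = forest.referral_pairs()
    if not pairs:
        return float("nan")
    y = forest.y_values()
    phat = float(y.mean())
    if phat in (0.0, 1.0):
        return float("nan")
    cross = sum(1 for i, j in pairs if y[i] != y[j])
    expected = len(pairs) * 2.0 * phat * (1.0 - phat)
    return cross / expected


def run_study(
    net: Network,
    s: int,
    r: int,
    methods: Sequence[str] = ("vhe",),
    seed: int = 0,
    branch_probs: Sequence[float] = DEFAULT_BRANCH_PROBS,
    with_replacement: bool = True,
    sbe_b: int = 1000,
    network_id: str = "network",
    sampling_variance_around: str = "truth",
) -> StudyResult:
    """Draw r branching RDS samples of size s and evaluate the estimators.

    ``methods`` may contain "vhe", "vhewbc", "vhehom2", "vhehom3", "sbe".
    Replicate-level estimator failures are recorded (NaN) rather than fatal.
    Replicate streams are spawned from ``seed`` so each replicate is an
    independent, individually reproducible stream.

    ``sampling_variance_around``: "truth" (the default MSE around the
    population mean) or "mean" (central variance of replicate estimates).
    """
    if r < 2:
        raise ValueError("need at least 2 replicates")
    unknown = set(methods) - (set(METHODS) | {"sbe"})
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    mu = float(net.y_vector().mean())
    root = np.random.SeedSequence(seed)
    rep_seeds = root.spawn(r)

    rows = []
    for rep, ss in enumerate(rep_seeds):
        sample_seed, boot_seed = ss.generate_state(2, dtype=np.uint64) >> np.uint64(33)  # < 2^31
        forest = rds_sample(net, s, tuple(branch_probs), with_replacement,
                            int(sample_seed))
        row: dict[str, object] = {"replicate": rep}
        row["homophily"] = homophily_ratio(forest)
        row["fom_verdict"] = fom_test(forest).verdict(0.05)
        est0 = None
        for name in methods:
            try:
                est = (sbe_variance(forest, b=sbe_b, seed=int(boot_seed))
                       if name == "sbe" else METHODS[name](forest))
                row[f"var_{name}"] = est.variance
                row[f"cover_{name}"] = coverage_hit(est, mu)
                est0 = est
            except Exception as exc:  # replicate-level failure, not fatal
                row[f"var_{name}"] = float("nan")
                row[f"cover_{name}"] = float("nan")
                row[f"error_{name}"] = repr(exc)
        row["mean"] = est0.mean if est0 is not None else _rds2(forest)
        rows.append(row)
    per = pd.DataFrame(rows)

    if sampling_variance_around == "truth":
        pop_var = empirical_sampling_variance(per["mean"].to_numpy(), mu)
    elif sampling_variance_around == "mean":
        pop_var = float(per["mean"].to_numpy().var())
    else:
        raise ValueError("sampling_variance_around must be 'truth' or 'mean'")

    srs = mu * (1 - mu) / s

    def summarize(block: pd.DataFrame) -> pd.DataFrame:
        out = []
        block_var = (
            empirical_sampling_variance(block["mean"].to_numpy(), mu)
            if len(block) >= 2 else float("nan")
        )
        for name in methods:
            v = block[f"var_{name}"].to_numpy(dtype=float)
            mean_v = float(np.nanmean(v)) if np.any(np.isfinite(v)) else float("nan")
            out.append({
                "method": name,
                "n_samples": int(np.isfinite(v).sum()),
                "mean_estimated_variance": mean_v,
                "bias": mean_v - pop_var,
                "ratio": mean_v / pop_var if pop_var > 0 else float("nan"),
                "coverage": float(np.nanmean(
                    block[f"cover_{name}"].to_numpy(dtype=float))),
                "empirical_design_effect": (block_var / srs if srs > 0
                                            else float("nan")),
                "estimated_design_effect": (mean_v / srs if srs > 0
                                            else float("nan")),
            })
        return pd.DataFrame(out)

    aggregates = summarize(per)
    panels = []
    for verdict, label in (("reject", "not_FOM"), ("may_be_FOM", "may_be_FOM")):
        mask = per["fom_verdict"].map(
            lambda v: v == "reject" if verdict == "reject" else v != "reject")
        block = per[mask]
        tab = summarize(block) if len(block) else pd.DataFrame()
        if len(tab):
            tab.insert(0, "panel", label)
            tab["n_panel"] = len(block)
            panels.append(tab)
    panels_df = pd.concat(panels, ignore_index=True) if panels else pd.DataFrame()

    return StudyResult(
        network_id=network_id, s=s, r=r, mu=mu, per_replicate=per,
        population_sampling_variance=pop_var, aggregates=aggregates,
        panels=panels_df,
    )


def _rds2(forest: RecruitmentForest) -> float:
    from .estimators import rds2_mean

    return rds2_mean(forest)


def bias_homophily_regression(
    per_sample: pd.DataFrame,
    standardize: bool = True,
    fixed_effects: bool = False,
    bias_col: str = "bias",
    homophily_col: str = "homophily",
    network_col: str = "network_id",
) -> dict[str, float]:
    """Regress per-sample variance-estimate bias on sample-level homophily.

    With ``standardize`` both variables are scaled to mean 0, sd 1 (so the
    slope is the XY-standardized coefficient); with ``fixed_effects`` both
    are first demeaned within network.  Rows with undefined homophily or
    bias are dropped listwise; the count is reported.
    """
    import statsmodels.api as sm

    tab = per_sample[[c for c in {bias_col, homophily_col, network_col}
                      if c in per_sample.columns]].copy()
    tab = tab.dropna(subset=[bias_col, homophily_col])
    n_dropped = len(per_sample) - len(tab)
    if fixed_effects:
        if network_col not in tab.columns or tab[network_col].nunique() < 2:
            raise ValueError("fixed effects require >= 2 networks")
        for col in (bias_col, homophily_col):
            tab[col] = tab[col] - tab.groupby(network_col)[col].transform("mean")
    x = tab[homophily_col].to_numpy(dtype=float)
    yv = tab[bias_col].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(yv) == 0:
        raise ValueError("zero variance in regressor or response")
    if standardize:
        x = (x - x.mean()) / x.std()
        yv = (yv - yv.mean()) / yv.std()
    X = np.column_stack([np.ones_like(x), x])
    fit = sm.OLS(yv, X).fit(cov_type="HC1")
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "se": float(fit.bse[1]),
        "r_squared": float(fit.rsquared),
        "n_obs": int(len(x)),
        "n_dropped": int(n_dropped),
    }


def cross_network_correlation(results: Iterable[StudyResult], method: str) -> float:
    """Pearson correlation across networks of mean estimated vs population variance."""
    est, pop = [], []
    for res in results:
        row = res.aggregates.loc[res.aggregates["method"] == method]
        if row.empty:
            raise ValueError(f"method {method!r} absent from {res.network_id}")
        est.append(float(row["mean_estimated_variance"].iloc[0]))
        pop.append(res.population_sampling_variance)
    if len(est) < 3:
        raise ValueError("need >= 3 networks")
    est_a, pop_a = np.asarray(est), np.asarray(pop)
    if est_a.std() == 0 or pop_a.std() == 0:
        return float("nan")
    return float(np.corrcoef(est_a, pop_a)[0, 1])
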