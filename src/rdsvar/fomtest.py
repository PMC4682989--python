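"""The first-order-Markov (FOM) diagnostic regression.

The variance estimators of the previous module assume the attribute sequence
along a recruitment chain is first-order Markov: the next value depends only
on the current one.  A sufficient condition for a violation is that the
two-step-back value still predicts the next value.  The diagnostic fits, by
OLS with heteroskedasticity-robust standard errors,

    resp = b0 + b1 * y_alter + b2 * y_ego + b3 * y_alter * y_ego + err

where each observation is an ordered adjacent pair (ego -> alter) — an edge
of the network, or a referral of the sample — and ``resp`` is the proportion
of the alter's alters (ego included) with y = 1.  Rejecting the joint null
b2 = b3 = 0 (robust Wald F, 2 numerator dof) says the network or sample is
not FOM; a failure to reject, or an incomputable regression (constant
response, single-category data), is recorded as "may be FOM".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graphs import Network
from .sampler import RecruitmentForest

__all__ = ["FOMTestResult", "neighborhood_observations", "fom_regression", "fom_test"]


@dataclass(frozen=True)
class FOMTestResult:
    beta: np.ndarray | None
    robust_cov: np.ndarray | None
    f_stat: float
    p_value: float
    n_obs: int

    def verdict(self, level: float = 0.05) -> str:
        """"reject" (not FOM), "may_be_FOM", or "undefined".

        An undefined test maps to "may be FOM" in downstream tabulations.
        """
        if np.isnan(self.p_value):
            return "undefined"
        return "reject" if self.p_value < level else "may_be_FOM"

    @classmethod
    def undefined(cls, n_obs: int) -> "FOMTestResult":
        return cls(beta=None, robust_cov=None, f_stat=float("nan"),
                   p_value=float("nan"), n_obs=n_obs)


def neighborhood_observations(
    source: Network | RecruitmentForest,
    level: str | None = None,
    ego_inclusion: str = "union",
) -> np.ndarray:
    """One observation per ordered adjacent pair (ego, alter).

    Returns an (n_obs, 3) array of (response, y_alter, y_ego).

    Network level: pairs are the two orientations of every edge; the alter's
    neighborhood is its network neighbors.  Sample level: pairs are
    recruiter->recruit referrals; the alter's neighborhood is its recruits
    plus its recruiter (the relations actually traversed by the sample).

    ``ego_inclusion`` controls how the ego enters the alter's neighborhood:

    * ``"union"`` (default) — counted once, even when already a neighbor;
      retains alters with no further contacts (pendants / non-recruiting
      respondents).  Note that this places the ego's own y inside the
      response, so the regression carries a mechanical dependence on y_ego
      of order 1/degree even when the value process is exactly first-order;
      the test is then a descriptive screen rather than a calibrated one.
    * ``"append"`` — ego added as an extra count regardless (multiset).
    * ``"exclude"`` — ego removed from the neighborhood; alters with no
      other contacts are dropped.  This removes the mechanical term (the
      response contains no y_ego), at the price of losing pendants.
    """
    if ego_inclusion not in ("union", "append", "exclude"):
        raise ValueError("ego_inclusion must be 'union', 'append' or 'exclude'")
    rows: list[tuple[float, float, float]] = []
    if isinstance(source, Network):
        if level not in (None, "network"):
            raise ValueError("a Network implies level='network'")
        ytot = {n: sum(source.y[v] for v in source.graph.neighbors(n))
                for n in source.nodes}
        for u, v in source.graph.edges:
            for ego, alter in ((u, v), (v, u)):
                tot = ytot[alter]
                cnt = source.degree(alter)
                if ego_inclusion == "append":  # ego is always a neighbor here
                    tot += source.y[ego]
                    cnt += 1
                elif ego_inclusion == "exclude":
                    tot -= source.y[ego]
                    cnt -= 1
                    if cnt == 0:
                        continue  # pendant alter: no neighborhood left
                rows.append((tot / cnt, float(source.y[alter]), float(source.y[ego])))
    elif isinstance(source, RecruitmentForest):
        if level not in (None, "sample"):
            raise ValueError("a RecruitmentForest implies level='sample'")
        y = source.y_values()
        recruits: dict[int, list[int]] = {}
        for rec, child in source.referral_pairs():
            recruits.setdefault(rec, []).append(child)
        for ego, alter in source.referral_pairs():
            members = list(recruits.get(alter, []))
            if ego_inclusion == "exclude":
                if not members:
                    continue  # non-recruiting alter: no neighborhood left
            else:  # union and append coincide: the recruiter appears once
                members.append(ego)
            tot, cnt = sum(int(y[k]) for k in members), len(members)
            rows.append((tot / cnt, float(y[alter]), float(y[ego])))
        if not rows:
            return np.empty((0, 3))
    else:
        raise TypeError(f"unsupported source type {type(source)!r}")
    return np.array(rows) if rows else np.empty((0, 3))


def fom_regression(obs: np.ndarray) -> FOMTestResult:
    """Robust OLS of the neighborhood proportion on (y_alter, y_ego, product).

    Uses HC1 covariance and the Wald F statistic for the 2-dof restriction
    b2 = b3 = 0 against F(2, n_obs - 4).  Rank-deficient designs (constant
    response or single-category data) give an undefined result.
    """
    import statsmodels.api as sm

    obs = np.asarray(obs, dtype=float)
    n = obs.shape[0]
    if n < 5:
        return FOMTestResult.undefined(n)
    resp, ya, ye = obs[:, 0], obs[:, 1], obs[:, 2]
    X = np.column_stack([np.ones(n), ya, ye, ya * ye])
    if np.linalg.matrix_rank(X) < 4 or np.ptp(resp) == 0.0:
        return FOMTestResult.undefined(n)
    import warnings

    fit = sm.OLS(resp, X).fit(cov_type="HC1")
    R = np.zeros((2, 4))
    R[0, 2] = 1.0
    R[1, 3] = 1.0
    try:
        with warnings.catch_warnings():
            # rank-deficient constraint covariance is handled via the result
            warnings.simplefilter("ignore")
            ft = fit.f_test(R)
        f_stat = float(np.squeeze(ft.fvalue))
        from scipy import stats

        p_value = float(stats.f.sf(f_stat, 2, n - 4))
    except Exception:
        return FOMTestResult.undefined(n)
    if not np.isfinite(f_stat):
        return FOMTestResult.undefined(n)
    return FOMTestResult(beta=fit.params, robust_cov=fit.cov_params(),
                         f_stat=f_stat, p_value=p_value, n_obs=n)


def fom_test(
    source: Network | RecruitmentForest,
    ego_inclusion: str = "union",
) -> FOMTestResult:
    """Convenience wrapper: observations plus regression in one call."""
    return fom_regression(neighborhood_observations(source, ego_inclusion=ego_inclusion))
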