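"""Curve estimators matching the three tests.

* :func:`nelson_aalen` — cause-specific cumulative hazard (matches the
  cause-specific log-rank test): only deaths of the cause of interest are
  events, all other deaths censor.
* :func:`aalen_johansen` — cumulative incidence function in the presence of
  the competing causes (matches Gray's test); unknown-cause deaths form a
  third competing state.
* :func:`peto_yearly_rates` — cumulative yearly rates in the overview
  (EBCTCG) style (matches Peto's test): a combined actuarial yearly death
  probability for the pooled arms is split between the arms by applying
  exp(+-b_j/2) to the yearly hazard, where b_j = (O-E)_j / V_j is the
  within-year log-rank estimate of the log rate ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from ._kernels import logrank_oe
from .compare import peto_reclassify
from .dataset import CAUSE_CODES, Status, TrialDataset

__all__ = ["CurveEstimate", "nelson_aalen", "aalen_johansen",
           "peto_yearly_rates", "curves_to_frame", "plot_curve_grid"]

_ARMS = {"control": 0, "treated": 1}


@dataclass
class CurveEstimate:
    """A nondecreasing step/point curve evaluated on an increasing grid."""

    times: np.ndarray
    values: np.ndarray
    arm: str
    cause: str
    kind: str

    def at(self, t: float) -> float:
        """Right-continuous evaluation of the curve at time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.values[idx]) if idx >= 0 else 0.0


def _select_arm(data: TrialDataset, arm: str):
    if arm == "combined":
        mask = np.ones(data.n, dtype=bool)
    else:
        try:
            mask = data.arm == _ARMS[arm]
        except KeyError:
            raise ValueError(f"arm must be control/treated/combined, got {arm!r}")
    if not mask.any():
        raise ValueError(f"arm {arm!r} is empty")
    return data.time[mask], data.status[mask]


def _event_codes(cause: str):
    if cause == "all":
        return [int(Status.CANCER), int(Status.NONCANCER), int(Status.UNKNOWN)]
    return [CAUSE_CODES[cause]]


def nelson_aalen(data: TrialDataset, cause: str = "all",
                 arm: str = "combined") -> CurveEstimate:
    """Nelson-Aalen cause-specific cumulative hazard, jumps d/n at event times."""
    time, status = _select_arm(data, arm)
    ev = np.isin(status, _event_codes(cause))
    ts = np.sort(time)
    ut, d = np.unique(np.sort(time[ev]), return_counts=True)
    n_at = ts.size - np.searchsorted(ts, ut, side="left")
    values = np.cumsum(d / n_at)
    return CurveEstimate(times=ut, values=values, arm=arm, cause=cause,
                         kind="nelson_aalen")


def aalen_johansen(data: TrialDataset, cause: str,
                   arm: str = "combined") -> CurveEstimate:
    """Aalen-Johansen cumulative incidence of one cause.

    Increments S(t-) * d_cause(t) / n(t) at each death time, with S the
    all-cause Kaplan-Meier in the same arm; for ``cause='all'`` this equals
    one minus the Kaplan-Meier estimate.
    """
    time, status = _select_arm(data, arm)
    any_death = status != int(Status.CENSORED)
    ts = np.sort(time)
    ut, d_all = np.unique(np.sort(time[any_death]), return_counts=True)
    n_at = ts.size - np.searchsorted(ts, ut, side="left")
    surv = np.cumprod(1.0 - d_all / n_at)
    s_left = np.concatenate(([1.0], surv[:-1]))
    ev = np.isin(status, _event_codes(cause))
    te = np.sort(time[ev])
    d_cause = np.searchsorted(te, ut, side="right") - np.searchsorted(te, ut, side="left")
    values = np.cumsum(s_left * d_cause / n_at)
    return CurveEstimate(times=ut, values=values, arm=arm, cause=cause,
                         kind="aalen_johansen")


def _year_logrank(time, event, group, lo, hi):
    """Within-interval log-rank contributions (O-E)_j, V_j.

    Subjects entering the interval at risk form the risk sets; events beyond
    ``hi`` are ignored (they belong to later intervals); the at-risk counts
    are the global ones, so summing over all intervals reproduces the whole
    log-rank sums.
    """
    in_win = (time >= lo) & (time < hi) & event
    if not in_win.any():
        return 0.0, 0.0
    # shift events outside the window to non-events, keep everyone's time
    return logrank_oe(time, in_win, group)[:2]


def peto_yearly_rates(data: TrialDataset, cause: str = "all",
                      year_length: float = 1.0
                      ) -> Tuple[CurveEstimate, CurveEstimate]:
    """Peto cumulative yearly rates for (control, treated).

    The data are first reclassified (post-recurrence and unknown-cause
    deaths become cancer deaths); for ``cause='noncancer'`` the
    recurrence-reclassified deaths are censored at their recurrence time.
    Per calendar
    year j the pooled actuarial death probability is q_j = d_j/(n_j - w_j/2)
    (w_j withdrawals in year j); the yearly hazard -log(1-q_j) is multiplied
    by exp(+-b_j/2) with b_j the within-year log-rank (O-E)/V to give the
    arm-specific yearly probabilities, cumulated on the product scale and
    reported at year boundaries.
    """
    if year_length <= 0:
        raise ValueError("year_length must be positive")
    if not ((data.arm == 0).any() and (data.arm == 1).any()):
        raise ValueError("both arms must be non-empty")
    rec = peto_reclassify(data) if cause != "all" else data.copy()
    time = rec.time
    status = rec.status
    if cause == "noncancer":
        from .compare import _recurrence_exit_mask
        exit_at_rec = _recurrence_exit_mask(data.status, data.rec_time)
        time = np.where(exit_at_rec, rec.rec_time, time)
        status = np.where(exit_at_rec, int(Status.CENSORED), status)
    event = np.isin(status, _event_codes(cause))

    max_t = float(time.max())
    n_years = max(1, int(math.ceil(max_t / year_length + 1e-12)))
    bounds = [0.0]
    cum = {0: [0.0], 1: [0.0]}
    surv = {0: 1.0, 1: 1.0}
    for j in range(n_years):
        lo, hi = j * year_length, (j + 1) * year_length
        at_risk = time >= lo
        n_j = int(at_risk.sum())
        if n_j == 0:
            break
        d_j = int((event & (time >= lo) & (time < hi)).sum())
        w_j = int((~event & (time >= lo) & (time < hi)).sum())
        denom = n_j - 0.5 * w_j
        q_j = d_j / denom if denom > 0 else 0.0
        if d_j == 0:
            b_j = 0.0
        else:
            oe_j, v_j = _year_logrank(time, event, data.arm, lo, hi)
            b_j = oe_j / v_j if v_j > 0 else 0.0
        q_j = min(q_j, 1.0)
        if q_j >= 1.0:
            q_arm = {0: 1.0, 1: 1.0}
        else:
            lam = -math.log1p(-q_j)
            q_arm = {0: 1.0 - math.exp(-lam * math.exp(-b_j / 2.0)),
                     1: 1.0 - math.exp(-lam * math.exp(+b_j / 2.0))}
        for g in (0, 1):
            surv[g] *= 1.0 - q_arm[g]
            cum[g].append(1.0 - surv[g])
        bounds.append(hi)
        if q_j >= 1.0:
            break
    times = np.asarray(bounds)
    control = CurveEstimate(times=times, values=np.asarray(cum[0]),
                            arm="control", cause=cause, kind="peto_yearly")
    treated = CurveEstimate(times=times, values=np.asarray(cum[1]),
                            arm="treated", cause=cause, kind="peto_yearly")
    return control, treated


def curves_to_frame(*curves: CurveEstimate) -> pd.DataFrame:
    """Serialize curves to the flat (kind, cause, arm, time, value) table."""
    parts = []
    for c in curves:
        parts.append(pd.DataFrame({"kind": c.kind, "cause": c.cause,
                                   "arm": c.arm, "time": c.times,
                                   "value": c.values}))
    if not parts:
        return pd.DataFrame(columns=["kind", "cause", "arm", "time", "value"])
    return pd.concat(parts, ignore_index=True)


def plot_curve_grid(data: TrialDataset, year_length: float = 1.0,
                    save_to: Optional[str] = None):
    """3x3 panel: rows = all/noncancer/cancer mortality, columns =
    Nelson-Aalen, Peto yearly rates, Aalen-Johansen, each by arm."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(3, 3, figsize=(11, 10), sharex=True)
    causes = ["all", "noncancer", "cancer"]
    for i, cause in enumerate(causes):
        for arm, color in (("control", "C0"), ("treated", "C1")):
            na = nelson_aalen(data, cause, arm)
            axes[i][0].step(na.times, na.values, where="post", color=color,
                            label=arm)
            aj = aalen_johansen(data, cause, arm)
            axes[i][2].step(aj.times, aj.values, where="post", color=color)
        pc, pt = peto_yearly_rates(data, cause, year_length)
        axes[i][1].plot(pc.times, pc.values, "o-", color="C0", ms=3)
        axes[i][1].plot(pt.times, pt.values, "o-", color="C1", ms=3)
        axes[i][0].set_ylabel(f"{cause} mortality")
    axes[0][0].set_title("Nelson-Aalen cumulative hazard")
    axes[0][1].set_title("Peto cumulative yearly rates")
    axes[0][2].set_title("Aalen-Johansen CIF")
    axes[0][0].legend()
    fig.tight_layout()
    if save_to:
        fig.savefig(save_to, dpi=120)
        plt.close(fig)
    return fig
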