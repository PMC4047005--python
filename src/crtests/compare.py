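"""Two-sample tests for a treatment effect on competing causes of death.

Three tests are provided, each returning a chi-square statistic on 1 df for
the two-arm comparison:

* :func:`logrank_cause_specific` — the log-rank test on the cause-specific
  hazard: deaths of the cause of interest are events, every other death
  (including unknown-cause deaths) is treated as independent censoring at
  its death time.
* :func:`gray_test` — the two-sample test for equality of cumulative
  incidence functions on the subdistribution hazard: subjects failing from
  a competing cause remain in the risk set (censoring-survival reweighted);
  unknown-cause deaths form a third competing event category.
* :func:`peto_subtraction_test` — the log-rank subtraction method: after
  reclassifying unknown-cause deaths and post-recurrence deaths as cancer
  deaths, O-E and V are computed for overall mortality and for non-cancer
  mortality; the cancer-death statistic is their difference.

All statistics are two-sided via the upper chi-square tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy.stats import chi2

from ._kernels import gray_oe, logrank_oe
from .dataset import CAUSE_CODES, Status, TrialDataset

__all__ = ["TestResult", "UndefinedStatisticError", "logrank_cause_specific",
           "gray_test", "peto_reclassify", "peto_subtraction_test",
           "reject_at_level", "run_all_tests"]


class UndefinedStatisticError(ValueError):
    """The test statistic is undefined on this dataset (no events / V<=0)."""


@dataclass(frozen=True)
class TestResult:
    """One chi-square test result with its O-E / variance components.

    ``observed_minus_expected`` is signed for the treated arm: positive
    values mean more treated-arm events than expected under the null.
    """

    statistic: float
    df: int
    p_value: float
    observed_minus_expected: float
    variance: float
    test: str = ""
    cause: str = ""


def _result(oe: float, var: float, test: str, cause: str) -> TestResult:
    if var <= 0.0:
        raise UndefinedStatisticError(
            f"{test}/{cause}: nonpositive variance ({var!r})")
    stat = oe * oe / var
    return TestResult(statistic=float(stat), df=1,
                      p_value=float(chi2.sf(stat, 1)),
                      observed_minus_expected=float(oe), variance=float(var),
                      test=test, cause=cause)


def _check_two_arms(data: TrialDataset) -> None:
    if not ((data.arm == 0).any() and (data.arm == 1).any()):
        raise UndefinedStatisticError("both arms must be non-empty")


def _cause_code(cause: str) -> int:
    try:
        return CAUSE_CODES[cause]
    except KeyError:
        raise ValueError(f"cause must be 'cancer' or 'noncancer', got {cause!r}")


def logrank_cause_specific(data: TrialDataset, cause: str) -> TestResult:
    """Cause-specific log-rank test; competing deaths censor at death time."""
    _check_two_arms(data)
    code = _cause_code(cause)
    event = data.status == code
    if not event.any():
        raise UndefinedStatisticError(f"no {cause} deaths in the data")
    oe, var, _ = logrank_oe(data.time, event, data.arm)
    return _result(oe, var, "CS", cause)


def gray_test(data: TrialDataset, cause: str) -> TestResult:
    """Gray's two-sample cumulative-incidence test (weight exponent 0)."""
    _check_two_arms(data)
    code = _cause_code(cause)
    if not (data.status == code).any():
        raise UndefinedStatisticError(f"no {cause} deaths in the data")
    oe, var, _ = gray_oe(data.time, data.status, data.arm, code)
    return _result(oe, var, "Gr", cause)


def peto_reclassify(data: TrialDataset) -> TrialDataset:
    """Reclassification step of the Peto method.

    Every unknown-cause death, and every non-cancer death preceded by an
    observed recurrence, is ascribed to the cancer; everything else is
    unchanged.
    """
    out = data.copy()
    has_rec = ~np.isnan(out.rec_time)
    to_cancer = (out.status == Status.UNKNOWN) | (
        (out.status == Status.NONCANCER) & has_rec)
    out.status[to_cancer] = int(Status.CANCER)
    return out


def _recurrence_exit_mask(status: np.ndarray, rec_time: np.ndarray) -> np.ndarray:
    """Subjects that leave the NCD analysis at their recurrence time.

    These are the deaths the reclassification ascribes to the cancer on the
    strength of a recurrence: declared non-cancer or unknown-cause deaths
    preceded by an observed recurrence.  From the recurrence on, their
    follow-up belongs to the cancer, so the NCD analysis censors them there.
    """
    has_rec = ~np.isnan(rec_time)
    return has_rec & ((status == Status.NONCANCER) | (status == Status.UNKNOWN))


def _peto_components(data: TrialDataset, exit_at_rec: np.ndarray):
    """(O-E, V) pairs for the all-cause and the NCD analyses of the
    (already reclassified) data."""
    any_death = data.status != Status.CENSORED
    oe_all, v_all, _ = logrank_oe(data.time, any_death, data.arm)
    # NCD analysis: recurrence-reclassified deaths censor at the recurrence
    # time; other deaths censor at their death time.
    t_ncd = np.where(exit_at_rec, data.rec_time, data.time)
    ev_ncd = (data.status == Status.NONCANCER) & ~exit_at_rec
    oe_ncd, v_ncd, _ = logrank_oe(t_ncd, ev_ncd, data.arm)
    return oe_all, v_all, oe_ncd, v_ncd


def peto_subtraction_test(data: TrialDataset) -> Tuple[TestResult, TestResult]:
    """Peto's log-rank subtraction test; returns (cancer, noncancer) results.

    The data are first put through :func:`peto_reclassify`.  The non-cancer
    statistic comes from a log-rank analysis in which the remaining
    non-cancer deaths are events and the recurrence-reclassified deaths are
    censored at their recurrence time.  The cancer statistic is obtained by
    subtraction from the all-cause analysis: O-E = (O-E)_all - (O-E)_NCD,
    V = V_all - V_NCD.
    """
    _check_two_arms(data)
    exit_at_rec = _recurrence_exit_mask(data.status, data.rec_time)
    rec = peto_reclassify(data)
    if not (rec.status == Status.NONCANCER).any():
        raise UndefinedStatisticError("no noncancer deaths after reclassification")
    if not (rec.status == Status.CANCER).any():
        raise UndefinedStatisticError("no cancer deaths after reclassification")
    oe_all, v_all, oe_ncd, v_ncd = _peto_components(rec, exit_at_rec)
    ncd = _result(oe_ncd, v_ncd, "Pe", "noncancer")
    cd = _result(oe_all - oe_ncd, v_all - v_ncd, "Pe", "cancer")
    return cd, ncd


def reject_at_level(result: TestResult, level: float) -> bool:
    """True iff the test rejects at the given two-sided nominal level."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    return bool(result.p_value < level)


# ---------------------------------------------------------------------------
# fast battery used by the Monte-Carlo study

_NAN = float("nan")


def _battery_statistics(time: np.ndarray, status: np.ndarray, arm: np.ndarray,
                        rec_time: np.ndarray) -> Dict[Tuple[str, str], float]:
    """All six (test, cause) chi-square statistics on raw arrays.

    Undefined statistics (no events, nonpositive variance) come back as NaN
    so the study runner can tally them as non-rejections.
    """
    out: Dict[Tuple[str, str], float] = {}

    for cause, code in CAUSE_CODES.items():
        ev = status == code
        if ev.any():
            oe, var, _ = logrank_oe(time, ev, arm)
            out[("CS", cause)] = oe * oe / var if var > 0 else _NAN
            oe, var, _ = gray_oe(time, status, arm, code)
            out[("Gr", cause)] = oe * oe / var if var > 0 else _NAN
        else:
            out[("CS", cause)] = _NAN
            out[("Gr", cause)] = _NAN

    # Peto, inlined to avoid a dataset copy
    has_rec = ~np.isnan(rec_time)
    exit_at_rec = has_rec & ((status == Status.NONCANCER)
                             | (status == Status.UNKNOWN))
    st = np.where((status == Status.UNKNOWN)
                  | ((status == Status.NONCANCER) & has_rec),
                  int(Status.CANCER), status)
    any_death = st != int(Status.CENSORED)
    ev_ncd = st == int(Status.NONCANCER)
    if any_death.any() and ev_ncd.any():
        oe_all, v_all, _ = logrank_oe(time, any_death, arm)
        t_ncd = np.where(exit_at_rec, rec_time, time)
        oe_ncd, v_ncd, _ = logrank_oe(t_ncd, ev_ncd, arm)
        out[("Pe", "noncancer")] = oe_ncd * oe_ncd / v_ncd if v_ncd > 0 else _NAN
        v_cd = v_all - v_ncd
        oe_cd = oe_all - oe_ncd
        out[("Pe", "cancer")] = oe_cd * oe_cd / v_cd if v_cd > 0 else _NAN
    else:
        out[("Pe", "noncancer")] = _NAN
        out[("Pe", "cancer")] = _NAN
    return out


def run_all_tests(data: TrialDataset) -> Dict[Tuple[str, str], TestResult]:
    """All three tests for both causes, as a {(test, cause): result} map."""
    results: Dict[Tuple[str, str], TestResult] = {}
    for cause in CAUSE_CODES:
        for fn, name in ((logrank_cause_specific, "CS"), (gray_test, "Gr")):
            try:
                results[(name, cause)] = fn(data, cause)
            except UndefinedStatisticError:
                pass
    try:
        cd, ncd = peto_subtraction_test(data)
        results[("Pe", "cancer")] = cd
        results[("Pe", "noncancer")] = ncd
    except UndefinedStatisticError:
        pass
    return results
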