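"""Comparison metrics: NRMSD, relaxation rates, vascular fingerprinting.

The normalized root-mean-square deviation between a simulated signal and a
reference is

    NRMSD = 100% * sqrt( mean_t |S(t) - S_ref(t)|^2 ) / sigma_ref,

with sigma_ref the standard deviation of the reference signal over time
(complex deviations; the metric is invariant to a common global phase).
Apparent relaxation-rate increases are read from single echo times,
dR2(') = -ln|S(TE)| / TE, giving "Boxerman plots" when traced against
vessel radius.  Vascular fingerprinting builds a dictionary of
temporal-average-normalized total-signal magnitudes over the radius sweep
and estimates the radius of a test signal as the dictionary entry with the
highest coefficient of determination R^2 (test as data, entry as model).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timecourse import SignalTimecourse

logger = logging.getLogger(__name__)

COMPARTMENTS = ("total", "ev", "iv")


def nrmsd(s: np.ndarray, s_ref: np.ndarray) -> float:
    """NRMSD (percent) between two equal-length complex timecourses."""
    s = np.asarray(s)
    s_ref = np.asarray(s_ref)
    if s.shape != s_ref.shape:
        raise ValueError("timecourses must have equal length")
    sigma_ref = np.sqrt(np.mean(np.abs(s_ref - s_ref.mean()) ** 2))
    if sigma_ref == 0:
        raise ZeroDivisionError("reference signal has zero variance")
    return float(100.0 * np.sqrt(np.mean(np.abs(s - s_ref) ** 2)) / sigma_ref)


def nrmsd_by_compartment(tc: SignalTimecourse,
                         tc_ref: SignalTimecourse) -> dict[str, float]:
    return {c: nrmsd(tc.compartment(c), tc_ref.compartment(c))
            for c in COMPARTMENTS}


def relaxation_rate(s, te_ms: float, times: np.ndarray | None = None,
                    which: str = "total") -> float:
    """Apparent rate -ln|S(TE)| / TE in s^-1.

    ``s`` may be a :class:`SignalTimecourse` (compartment selected by
    ``which``), an array sampled at ``times`` (ms), or the scalar |S(TE)|.
    """
    if isinstance(s, SignalTimecourse):
        mag = abs(s.at_time(te_ms, which))
    elif np.ndim(s) == 0:
        mag = abs(complex(s))
    else:
        if times is None:
            raise ValueError("times (ms) required with an array signal")
        idx = int(np.argmin(np.abs(np.asarray(times) - te_ms)))
        if abs(times[idx] - te_ms) > 1e-9:
            raise ValueError(f"TE {te_ms} ms not on the sampled grid")
        mag = abs(s[idx])
    if mag == 0:
        raise ZeroDivisionError("|S(TE)| = 0 has no finite rate")
    return float(-np.log(mag) / (te_ms * 1e-3))


def boxerman(result, approach: str, te_ge: float | None = None,
             te_se: float | None = None) -> pd.DataFrame:
    """Relaxation rates versus radius for one approach.

    For each radius and compartment the table holds the rate of the
    voxel-mean complex signal (``dr2p`` for the gradient echo, ``dr2`` for
    the spin echo) plus the across-voxel mean and standard deviation of the
    per-voxel rates; the SD is NaN for single-voxel approaches.
    """
    te_ge = te_ge if te_ge is not None else result.config.te_gradient_echo
    te_se = te_se if te_se is not None else result.config.te_spin_echo
    radii = result.radii(approach)
    if not radii:
        raise KeyError(f"no results for approach {approach!r}")
    rows = []
    for radius in radii:
        mean_tc = result.mean_signal(approach, radius)
        voxel_tcs = [result.get(approach, radius, v)
                     for v in result.voxel_ids(approach)]
        for comp in COMPARTMENTS:
            per_voxel_ge = [relaxation_rate(tc, te_ge, which=comp)
                            for tc in voxel_tcs]
            per_voxel_se = [relaxation_rate(tc, te_se, which=comp)
                            for tc in voxel_tcs]
            multi = len(voxel_tcs) > 1
            rows.append({
                "approach": approach, "radius_um": radius,
                "compartment": comp,
                "dr2p": relaxation_rate(mean_tc, te_ge, which=comp),
                "dr2": relaxation_rate(mean_tc, te_se, which=comp),
                "dr2p_mean": float(np.mean(per_voxel_ge)),
                "dr2p_sd": float(np.std(per_voxel_ge, ddof=1)) if multi
                else np.nan,
                "dr2_mean": float(np.mean(per_voxel_se)),
                "dr2_sd": float(np.std(per_voxel_se, ddof=1)) if multi
                else np.nan,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fingerprinting
# ---------------------------------------------------------------------------

def normalize_by_temporal_average(magnitude: np.ndarray) -> np.ndarray:
    mean = np.mean(magnitude)
    if mean == 0:
        raise ZeroDivisionError("zero temporal mean")
    return np.asarray(magnitude) / mean


@dataclass
class FingerprintDictionary:
    """Lookup table of normalized total-signal magnitudes per radius."""

    approach: str
    radii: np.ndarray                 # um, strictly increasing
    entries: np.ndarray               # (n_radii, n_times)
    temporal_means: np.ndarray        # normalization record

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.radii) > 0):
            raise ValueError("radii must be strictly increasing")
        if self.entries.shape[0] != len(self.radii):
            raise ValueError("one entry per radius required")


def build_dictionary(result, approach: str) -> FingerprintDictionary:
    """Dictionary from the voxel-mean total signals of one approach.

    Each entry is |S_tot(t)| of the voxel-mean signal, divided by its own
    temporal average, over every simulated time point.
    """
    radii = np.array(result.radii(approach), dtype=float)
    entries, means = [], []
    for radius in radii:
        mag = np.abs(result.mean_signal(approach, radius).s_tot)
        means.append(np.mean(mag))
        entries.append(normalize_by_temporal_average(mag))
    return FingerprintDictionary(approach=approach, radii=radii,
                                 entries=np.array(entries),
                                 temporal_means=np.array(means))


def fingerprint_match(test_signal: np.ndarray,
                      dictionary: FingerprintDictionary
                      ) -> tuple[float, np.ndarray]:
    """Best-matching dictionary radius by the coefficient of determination.

    ``test_signal`` must be normalized exactly like the dictionary entries
    (use :func:`normalize_by_temporal_average` on the magnitude).  R^2
    treats the test as the data and each entry as the model:
    R^2 = 1 - sum (test-entry)^2 / sum (test - mean(test))^2.  Ties go to
    the smaller radius (logged).
    """
    test = np.asarray(test_signal, dtype=float)
    ss_tot = np.sum((test - test.mean()) ** 2)
    if ss_tot == 0:
        raise ZeroDivisionError("test signal has zero variance")
    ss_res = np.sum((dictionary.entries - test) ** 2, axis=1)
    r2 = 1.0 - ss_res / ss_tot
    best = int(np.argmax(r2))          # first maximum = smallest radius
    if np.sum(r2 == r2[best]) > 1:
        logger.warning("fingerprint tie at R^2=%.6f; choosing the smaller "
                       "radius %.3g um", r2[best], dictionary.radii[best])
    return float(dictionary.radii[best]), r2


def fingerprint_radii(result, test_approach: str,
                      dictionary: FingerprintDictionary
                      ) -> pd.DataFrame:
    """Match every radius of a test approach against a dictionary."""
    rows = []
    for radius in result.radii(test_approach):
        mag = np.abs(result.mean_signal(test_approach, radius).s_tot)
        test = normalize_by_temporal_average(mag)
        est, r2 = fingerprint_match(test, dictionary)
        rows.append({"true_radius_um": radius, "estimated_radius_um": est,
                     "best_r2": float(np.max(r2))})
    return pd.DataFrame(rows)


def fingerprint_error_report(estimates, truths) -> tuple[pd.DataFrame, dict]:
    """Per-radius absolute percent errors plus summary statistics.

    Returns (table, summary) where summary holds the mean and max absolute
    percent error and the count of mis-estimated radii.
    """
    est = np.asarray(estimates, dtype=float)
    true = np.asarray(truths, dtype=float)
    if est.shape != true.shape:
        raise ValueError("estimates and truths must have equal length")
    err = 100.0 * np.abs(est - true) / true
    table = pd.DataFrame({"true_radius_um": true,
                          "estimated_radius_um": est,
                          "abs_percent_error": err})
    summary = {"mean_abs_percent_error": float(err.mean()),
               "max_abs_percent_error": float(err.max()),
               "n_erroneous": int(np.sum(est != true)),
               "n_radii": int(len(true))}
    return table, summary
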