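"""Event gating: live-cell scatter gate, 7-AAD viability gate, GFP
population selection and order-statistic background calibration.

The gating strategy mirrors the standard cell-based-assay workflow:

1. identify intact cells on forward/side scatter (debris excluded by an
   FSC floor plus a robust ellipsoidal gate on log scatter);
2. exclude dead cells by 7-AAD;
3. select the analysis population by GFP — the GFP-negative population on
   the parental line, the GFP-positive (transfected, reporter-expressing)
   population on the transfected line;
4. calibrate the PE background threshold on a no-serum, secondary-only
   control so that 0.5% of its gated population lies strictly above it.

All thresholds operate on raw linear intensities; logs are used only for
geometry fitting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import GatingConfig
from .errors import (
    CalibrationError,
    DegenerateGeometryError,
    InsufficientEventsError,
    InsufficientPopulationError,
    ParameterError,
)
from .io import EventTable


@dataclass
class GateMask:
    """Boolean event mask for one gating stage.

    Masks of successive stages are nested: population <= viable <= live.
    """

    mask: np.ndarray
    stage: str  # live | viable | population

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_retained(self) -> int:
        return int(self.mask.sum())

    @property
    def retained_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0


@dataclass
class ThresholdSet:
    """Calibrated gate boundaries for one assay (both cell lines)."""

    gfp_cutoff_parental: float
    gfp_cutoff_transfected: float
    pe_threshold_parental: float
    pe_threshold_transfected: float
    aad_threshold: float
    gfp_mode: str = "different"

    def __post_init__(self) -> None:
        values = (self.gfp_cutoff_parental, self.gfp_cutoff_transfected,
                  self.pe_threshold_parental, self.pe_threshold_transfected,
                  self.aad_threshold)
        if not all(math.isfinite(v) for v in values):
            raise ParameterError("all thresholds must be finite")
        if self.gfp_mode == "same" and \
                self.gfp_cutoff_parental != self.gfp_cutoff_transfected:
            raise ParameterError("gfp_mode='same' requires equal GFP cutoffs")


def order_statistic_threshold(values: np.ndarray, rate: float) -> float:
    """Smallest observed value ``t`` such that at most ``floor(rate*n)``
    events lie strictly above ``t``.

    This is the (n - floor(rate*n))-th order statistic (1-based,
    ascending) — the calibration rule shared by the PE background, the
    parental GFP cut-off and the optional 7-AAD calibration.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n == 0:
        raise CalibrationError("cannot calibrate a threshold from zero events")
    if not 0 <= rate < 1:
        raise ParameterError("rate must be in [0, 1)")
    k = int(math.floor(rate * n))
    return float(np.sort(values, kind="stable")[n - k - 1])


# ---------------------------------------------------------------------------
# Scatter (live-cell) gate
# ---------------------------------------------------------------------------

# consistency factor for a moment estimate computed from the central `q`
# mass of a bivariate normal: cov_trimmed underestimates cov by
# P(chi2_4 <= r2)/q where r2 = chi2_2 quantile at q
def _trim_consistency(q: float) -> float:
    r2 = stats.chi2.ppf(q, df=2)
    return q / stats.chi2.cdf(r2, df=4)


def gate_live(table: EventTable, config: GatingConfig | None = None) -> GateMask:
    """Scatter gate: drop sub-FSC-floor debris, then retain events inside a
    robust ellipsoid on log-FSC/log-SSC covering ``config.central_mass``.

    The location/scatter estimate is an iteratively trimmed mean and
    covariance (with the truncation-consistency correction), refit
    ``config.robust_iterations`` times so debris and stragglers do not
    inflate the ellipse.
    """
    config = config or GatingConfig()
    n = table.n_events
    if n < config.min_events:
        raise InsufficientEventsError(
            f"{table.sample_id}: {n} events < minimum {config.min_events}")

    fsc = table.channel("FSC")
    ssc = table.channel("SSC")
    above_floor = fsc >= config.fsc_floor
    if above_floor.sum() < config.min_events:
        raise InsufficientEventsError(
            f"{table.sample_id}: fewer than {config.min_events} events above "
            f"the FSC floor {config.fsc_floor}")

    X = np.log(np.column_stack([fsc, ssc])[above_floor] + 1.0)
    r2 = stats.chi2.ppf(config.central_mass, df=2)
    correction = _trim_consistency(config.central_mass)
    inlier = np.ones(len(X), dtype=bool)
    mean = X.mean(axis=0)
    cov = np.cov(X.T)
    for iteration in range(config.robust_iterations):
        if not np.all(np.isfinite(cov)) or np.linalg.det(cov) <= 1e-12:
            raise DegenerateGeometryError(
                f"{table.sample_id}: singular scatter geometry")
        d2 = _mahalanobis_sq(X, mean, cov)
        inlier = d2 <= r2
        if inlier.sum() < config.min_events:
            raise InsufficientEventsError(
                f"{table.sample_id}: robust scatter fit collapsed")
        mean = X[inlier].mean(axis=0)
        cov = np.cov(X[inlier].T) * correction

    if not np.all(np.isfinite(cov)) or np.linalg.det(cov) <= 1e-12:
        raise DegenerateGeometryError(f"{table.sample_id}: singular scatter geometry")
    d2 = _mahalanobis_sq(X, mean, cov)
    mask = np.zeros(n, dtype=bool)
    mask[np.flatnonzero(above_floor)[d2 <= r2]] = True
    return GateMask(mask=mask, stage="live")


def _mahalanobis_sq(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    delta = X - mean
    solved = np.linalg.solve(cov, delta.T)
    return np.einsum("ij,ji->i", delta, solved)


# ---------------------------------------------------------------------------
# Viability gate
# ---------------------------------------------------------------------------

def gate_viable(table: EventTable, mask_in: GateMask,
                aad_threshold: float) -> GateMask:
    """Exclude dead cells: retain live-gated events with 7-AAD intensity at
    or below ``aad_threshold``."""
    if mask_in.stage != "live":
        raise ParameterError(f"gate_viable expects a live-stage mask, "
                             f"got {mask_in.stage!r}")
    if not math.isfinite(aad_threshold):
        raise ParameterError("aad_threshold must be finite")
    mask = mask_in.mask & (table.channel("AAD") <= aad_threshold)
    return GateMask(mask=mask, stage="viable")


def calibrate_aad_threshold(control: EventTable,
                            live_mask: GateMask | None = None,
                            rate: float = 0.005) -> float:
    """Viability threshold from an unstained (or otherwise dead-free)
    control: the smallest value leaving at most ``floor(rate*n)`` of the
    live-gated control events above it — the same order-statistic rule as
    the PE background, applied to the 7-AAD channel."""
    aad = control.channel("AAD")
    if live_mask is not None:
        aad = aad[live_mask.mask]
    return order_statistic_threshold(aad, rate)


# ---------------------------------------------------------------------------
# GFP population selection
# ---------------------------------------------------------------------------

def _otsu_split(log_values: np.ndarray, bins: int = 256) -> tuple[float, float]:
    """Two-component 1-D split minimising within-class variance.

    Returns (threshold on the log scale, Ashman separation D of the two
    classes).  D below ~3 indicates there is no resolvable second mode.
    """
    hist, edges = np.histogram(log_values, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    w = hist.astype(float)
    total = w.sum()
    cum_w = np.cumsum(w)
    cum_wx = np.cumsum(w * centers)
    cum_wx2 = np.cumsum(w * centers**2)

    best_score, best_i = np.inf, None
    for i in range(1, bins):
        w0, w1 = cum_w[i - 1], total - cum_w[i - 1]
        if w0 < 1 or w1 < 1:
            continue
        m0 = cum_wx[i - 1] / w0
        m1 = (cum_wx[-1] - cum_wx[i - 1]) / w1
        v0 = cum_wx2[i - 1] / w0 - m0**2
        v1 = (cum_wx2[-1] - cum_wx2[i - 1]) / w1 - m1**2
        score = w0 * v0 + w1 * v1
        if score < best_score:
            best_score, best_i = score, i
    if best_i is None:
        raise CalibrationError("degenerate GFP distribution")

    thr = edges[best_i]
    lo, hi = log_values[log_values < thr], log_values[log_values >= thr]
    s_lo = lo.std() if lo.size > 1 else 0.0
    s_hi = hi.std() if hi.size > 1 else 0.0
    pooled = math.sqrt((s_lo**2 + s_hi**2) / 2.0)
    d = abs(hi.mean() - lo.mean()) / pooled if pooled > 0 else 0.0
    return float(thr), float(d)


#: minimum Ashman separation for the transfected GFP split to count as
#: bimodal (a split of a single log-normal mode lands near D ~ 2.7)
MIN_GFP_SEPARATION = 3.0
MIN_GFP_CLASS_FRACTION = 0.02


def calibrate_gfp_thresholds(parental_control: EventTable,
                             transfected_control: EventTable,
                             mode: str = "different",
                             parental_mask: GateMask | None = None,
                             transfected_mask: GateMask | None = None,
                             tail_rate: float = 0.001) -> tuple[float, float]:
    """GFP cut-off lines from the two secondary-only controls.

    ``different`` mode (the default protocol): the parental cut-off is the
    99.9th-percentile order statistic of the parental control's GFP (the
    GFP-negative gate lies below it); the transfected cut-off is the valley
    (antimode) of a two-component split of the transfected control's
    log-GFP, separating reporter-expressing from non-expressing cells.

    ``same`` mode: both cut-offs are the parental order statistic.

    Controls should be gated live + viable first (pass the masks).
    """
    if mode not in ("different", "same"):
        raise ParameterError(f"unknown gfp_mode {mode!r}")

    gfp_par = parental_control.channel("GFP")
    if parental_mask is not None:
        gfp_par = gfp_par[parental_mask.mask]
    cutoff_parental = order_statistic_threshold(gfp_par, tail_rate)
    if mode == "same":
        return cutoff_parental, cutoff_parental

    gfp_tr = transfected_control.channel("GFP")
    if transfected_mask is not None:
        gfp_tr = gfp_tr[transfected_mask.mask]
    if gfp_tr.size < 2:
        raise CalibrationError("too few transfected-control events for a GFP split")
    log_thr, separation = _otsu_split(np.log(gfp_tr + 1.0))
    frac_hi = float((np.log(gfp_tr + 1.0) >= log_thr).mean())
    if separation < MIN_GFP_SEPARATION or \
            not MIN_GFP_CLASS_FRACTION <= frac_hi <= 1 - MIN_GFP_CLASS_FRACTION:
        raise CalibrationError(
            f"transfected control GFP appears unimodal (separation "
            f"D={separation:.2f}, positive fraction {frac_hi:.3f}); "
            f"no expressing population to gate")
    return cutoff_parental, float(np.exp(log_thr) - 1.0)


def select_population(table: EventTable, thresholds: ThresholdSet,
                      mask_in: GateMask, min_population: int = 100) -> GateMask:
    """Select the analysis population within the viable gate: GFP-negative
    events (below the parental cut-off) on the parental line, GFP-positive
    events (above the transfected cut-off) on the transfected line."""
    if mask_in.stage != "viable":
        raise ParameterError(f"select_population expects a viable-stage mask, "
                             f"got {mask_in.stage!r}")
    gfp = table.channel("GFP")
    if table.cell_line == "parental":
        selected = gfp < thresholds.gfp_cutoff_parental
    else:
        selected = gfp > thresholds.gfp_cutoff_transfected
    mask = mask_in.mask & selected
    if mask.sum() < min_population:
        raise InsufficientPopulationError(
            f"{table.sample_id}: gated population has {int(mask.sum())} events "
            f"(< {min_population}); the PE fraction would be unstable")
    return GateMask(mask=mask, stage="population")


# ---------------------------------------------------------------------------
# PE background
# ---------------------------------------------------------------------------

def calibrate_pe_background(control: EventTable, population_mask: GateMask,
                            rate: float = 0.005) -> float:
    """PE background threshold from a no-serum, secondary-only control,
    calibrated within its fully gated population so that at most
    ``floor(rate*n)`` events lie strictly above it (0.5% by default).

    Calibrated independently per cell line: the transfected line carries a
    higher PE background because of GFP spillover, so each line gets its
    own threshold.
    """
    pe = control.channel("PE")[population_mask.mask]
    if pe.size == 0:
        raise CalibrationError(
            f"{control.sample_id}: empty population mask for PE calibration")
    return order_statistic_threshold(pe, rate)


@dataclass
class GatingReport:
    """Per-sample audit of events surviving each gate."""

    sample_id: str
    n_events: int
    live_fraction: float
    viable_fraction: float
    population_fraction: float

    @staticmethod
    def header() -> str:
        return "sample_id\tn_events\tlive_pct\tviable_pct\tpopulation_pct"

    def row(self) -> str:
        return (f"{self.sample_id}\t{self.n_events}\t"
                f"{100 * self.live_fraction:.2f}\t"
                f"{100 * self.viable_fraction:.2f}\t"
                f"{100 * self.population_fraction:.2f}")
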