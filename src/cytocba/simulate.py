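"""Synthetic cytometry with known ground truth.

The generator emulates the event-level structure of the assay: a debris
population at low scatter, a dead (7-AAD-high) population, and live cells
whose GFP splits the transfected line into reporter-expressing and
non-expressing cells.  Serum IgG binding is read out on PE through a
Langmuir saturation law, so that at high antibody titre the PE signal —
and hence the antibody index — is stable across serum dilutions and cell
numbers, which is the assay's central operating characteristic.

PE model for event *i* (all intensities in arbitrary linear units)::

    PE_i = (AF_i * (1 + B_ns * s(g * c)) + sec
                 + 1{expressing_i} * A * s(t * c)) * eta_i + spill * GFP_i

    s(x) = x / (K + x)          Langmuir saturation
    c    = 1 / dilution          serum concentration
    t    = antigen-specific antibody titre (0 for seronegative serum)
    g    = total serum immunoglobulin (nonspecific binding, any serum)
    sec  = secondary-only nonspecific term (present whenever the
           PE-labelled secondary antibody is applied)
    eta  = multiplicative log-normal measurement noise

Nonspecific serum binding is proportional to each cell's autofluorescence
(cell size / surface heterogeneity), so it widens nobody's tail: the
brightest cells bind the most IgG, which is what keeps the PE-positive
fraction of a serum-exposed sample a stable multiple of the 0.5%
background tail.

Both the specific and the nonspecific serum terms saturate, mirroring
antibody excess at working dilutions: a seronegative serum still binds
nonspecifically (which is why its parental PE fraction exceeds the 0.5%
background), while only the antigen-specific term separates the
transfected line.  GFP spillover into PE gives the transfected line its
higher PE background, which the per-line background calibration absorbs.

Scale: the generator's default 10^4 events stand in for the 5.0 x 10^6
cells of the bench protocol (2,000 events per million cells); serum at
1:100 and secondary antibody at 1:1000 match the protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import (
    AssayRun,
    EventTable,
    ManifestEntry,
    SampleManifest,
    save_manifest,
    write_events_csv,
    write_fcs,
)

POPULATIONS = ("debris", "dead", "live")


@dataclass
class SimulationParams:
    """Full parameterisation of one simulated sample.

    Scatter/fluorescence distributions are log-normal (standard for
    cytometry); means are given on the log scale.
    """

    n_events: int = 10_000
    debris_fraction: float = 0.10
    dead_fraction: float = 0.05
    transfection_efficiency: float = 0.60

    # log-FSC/log-SSC mean per population and 2x2 covariance (shared shape,
    # debris more diffuse)
    scatter_mean: dict = field(default_factory=lambda: {
        "live": (11.0, 10.0),
        "dead": (10.8, 10.1),
        "debris": (8.0, 7.8),
    })
    scatter_cov: dict = field(default_factory=lambda: {
        "live": ((0.0625, 0.025), (0.025, 0.0625)),
        "dead": ((0.09, 0.03), (0.03, 0.09)),
        "debris": ((0.25, 0.0), (0.0, 0.25)),
    })

    # GFP: non-expressing vs reporter-expressing cells
    gfp_mu_neg: float = math.log(50.0)
    gfp_sigma_neg: float = 0.5
    gfp_mu_pos: float = math.log(5000.0)
    gfp_sigma_pos: float = 0.6

    # PE model (see module docstring)
    pe_mu_af: float = math.log(80.0)
    pe_sigma_af: float = 0.5
    pe_nonspecific_relative: float = 0.95     # B_ns, x autofluorescence
    pe_specific_amplitude: float = 5000.0     # A
    pe_half_saturation: float = 1e-4          # K
    pe_noise_sigma: float = 0.25              # eta
    pe_secondary_coeff: float = 2000.0        # sec = coeff / secondary_dilution
    gfp_pe_spill: float = 0.013               # GFP -> PE spillover

    # 7-AAD: live-low, dead-high
    aad_mu_live: float = math.log(60.0)
    aad_sigma_live: float = 0.4
    aad_mu_dead: float = math.log(6000.0)
    aad_sigma_dead: float = 0.4

    # serum
    antibody_titer: float = 0.0   # antigen-specific titre t (arbitrary units)
    serum_ig: float = 10.0        # total-IgG nonspecific load g
    dilution: int = 100           # reciprocal serum dilution
    secondary_dilution: int = 1000

    cell_count_nominal: int = 5_000_000
    events_per_million: float = 2000.0
    control_n_events: int = 20_000  # background controls are a batch-level
                                    # acquisition, deeper than any one test
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ParameterError("n_events must be >= 0")
        if self.control_n_events < 0:
            raise ParameterError("control_n_events must be >= 0")
        for name in ("debris_fraction", "dead_fraction", "transfection_efficiency"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.debris_fraction + self.dead_fraction > 1.0:
            raise ParameterError("debris_fraction + dead_fraction must be <= 1")
        for name in ("gfp_sigma_neg", "gfp_sigma_pos", "pe_sigma_af",
                     "pe_noise_sigma", "aad_sigma_live", "aad_sigma_dead"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if self.pe_half_saturation <= 0:
            raise ParameterError("pe_half_saturation (K) must be > 0")
        if self.pe_nonspecific_relative < 0 or self.pe_specific_amplitude < 0:
            raise ParameterError("binding amplitudes must be >= 0")
        if self.antibody_titer < 0:
            raise ParameterError("antibody_titer must be >= 0")
        if self.dilution <= 0 or self.secondary_dilution <= 0:
            raise ParameterError("dilutions must be positive reciprocals")


@dataclass
class GroundTruth:
    """Per-event simulator labels plus the per-sample serostatus."""

    population: np.ndarray   # str array over POPULATIONS
    expressing: np.ndarray   # bool array
    true_serostatus: bool

    def fraction(self, population: str) -> float:
        return float((self.population == population).mean())


def _rng(seed: int, *stream: int) -> np.random.Generator:
    """Counter-based stream split: one master seed, deterministic per-sample
    substreams independent of generation order."""
    return np.random.default_rng([int(seed)] + [int(s) for s in stream])


def _saturation(x: float, k: float) -> float:
    return x / (k + x) if x > 0 else 0.0


def simulate_sample(params: SimulationParams, cell_line: str, antigen: str,
                    serum_id: str | None = None, role: str = "test",
                    stream: int = 0) -> tuple[EventTable, GroundTruth]:
    """Draw one sample's events.

    ``role`` selects the serum/secondary composition: ``test`` applies
    serum (titre + nonspecific IgG) and secondary antibody;
    ``no_serum_with_secondary`` applies the secondary only (the background
    calibration control); ``no_serum_no_secondary`` leaves autofluorescence
    and spillover only.  The parental line never expresses antigen
    (transfection efficiency treated as 0).  Deterministic given
    (params.seed, stream).
    """
    if cell_line not in ("parental", "transfected"):
        raise ParameterError(f"unknown cell_line {cell_line!r}")
    rng = _rng(params.seed, 0, stream)
    n = params.n_events

    u = rng.random(n)
    population = np.full(n, "live", dtype=object)
    population[u < params.debris_fraction] = "debris"
    population[(u >= params.debris_fraction)
               & (u < params.debris_fraction + params.dead_fraction)] = "dead"

    fsc = np.empty(n)
    ssc = np.empty(n)
    for pop in POPULATIONS:
        idx = population == pop
        if not idx.any():
            continue
        xy = rng.multivariate_normal(np.asarray(params.scatter_mean[pop], float),
                                     np.asarray(params.scatter_cov[pop], float),
                                     size=int(idx.sum()))
        fsc[idx] = np.exp(xy[:, 0])
        ssc[idx] = np.exp(xy[:, 1])

    efficiency = params.transfection_efficiency if cell_line == "transfected" else 0.0
    expressing = (population == "live") & (rng.random(n) < efficiency)
    gfp = np.where(
        expressing,
        rng.lognormal(params.gfp_mu_pos, params.gfp_sigma_pos, n),
        rng.lognormal(params.gfp_mu_neg, params.gfp_sigma_neg, n),
    )

    if role == "test":
        c = 1.0 / params.dilution
        titer, ig = params.antibody_titer, params.serum_ig
        secondary = True
    elif role == "no_serum_with_secondary":
        titer = ig = 0.0
        c = 0.0
        secondary = True
    elif role == "no_serum_no_secondary":
        titer = ig = 0.0
        c = 0.0
        secondary = False
    else:
        raise ParameterError(f"unknown role {role!r}")

    k = params.pe_half_saturation
    base = rng.lognormal(params.pe_mu_af, params.pe_sigma_af, n)
    base = base * (1.0 + params.pe_nonspecific_relative * _saturation(ig * c, k))
    if secondary:
        base = base + params.pe_secondary_coeff / params.secondary_dilution
    base = base + np.where(expressing,
                           params.pe_specific_amplitude * _saturation(titer * c, k),
                           0.0)
    noise = rng.lognormal(0.0, params.pe_noise_sigma, n)
    pe = base * noise + params.gfp_pe_spill * gfp

    aad = np.where(
        population == "dead",
        rng.lognormal(params.aad_mu_dead, params.aad_sigma_dead, n),
        rng.lognormal(params.aad_mu_live, params.aad_sigma_live, n),
    )

    sample_id = "_".join([
        serum_id if serum_id else "noserum",
        cell_line, antigen,
        f"d{params.dilution}" if role == "test" else role,
    ])
    table = EventTable(
        sample_id=sample_id,
        cell_line=cell_line,
        antigen=antigen,
        intensities=np.column_stack([fsc, ssc, gfp, pe, aad]),
        serum_id=serum_id if role == "test" else None,
        dilution=params.dilution if role == "test" else None,
        cell_count_nominal=params.cell_count_nominal,
    )
    truth = GroundTruth(
        population=np.asarray(population, dtype=str),
        expressing=expressing,
        true_serostatus=params.antibody_titer > 0 and role == "test",
    )
    return table, truth


def simulate_assay(params: SimulationParams, antigen: str, serum_id: str,
                   stream_base: int = 0) -> AssayRun:
    """One full assay unit: test samples on both cell lines plus the two
    secondary-only background controls, on separate seed substreams."""
    ctl_params = replace(params, n_events=params.control_n_events)
    test_par, truth_tp = simulate_sample(params, "parental", antigen, serum_id,
                                         role="test", stream=stream_base + 0)
    test_tr, truth_tt = simulate_sample(params, "transfected", antigen, serum_id,
                                        role="test", stream=stream_base + 1)
    ctl_par, truth_cp = simulate_sample(ctl_params, "parental", antigen, None,
                                        role="no_serum_with_secondary",
                                        stream=stream_base + 2)
    ctl_tr, truth_ct = simulate_sample(ctl_params, "transfected", antigen, None,
                                       role="no_serum_with_secondary",
                                       stream=stream_base + 3)
    return AssayRun(
        serum_id=serum_id, antigen=antigen, dilution=params.dilution,
        test_parental=test_par, test_transfected=test_tr,
        control_parental=ctl_par, control_transfected=ctl_tr,
        ground_truth={
            "true_serostatus": params.antibody_titer > 0,
            "test_parental": truth_tp, "test_transfected": truth_tt,
            "control_parental": truth_cp, "control_transfected": truth_ct,
        },
    )


def simulate_dilution_series(params: SimulationParams, antigen: str = "titin",
                             serum_id: str = "serum",
                             dilutions: tuple[int, ...] = (100, 500, 1000),
                             replicates: int = 1) -> list[AssayRun]:
    """One assay per (dilution, replicate), identical serum titre
    throughout.  Defaults follow the bench validation design
    (1:100, 1:500, 1:1000)."""
    if not dilutions:
        raise ParameterError("dilutions must be non-empty")
    if any(d <= 0 for d in dilutions):
        raise ParameterError("dilutions must be positive reciprocals")
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    runs = []
    for i, dilution in enumerate(dilutions):
        for rep in range(replicates):
            run = simulate_assay(
                replace(params, dilution=int(dilution)), antigen, serum_id,
                stream_base=4 * (i * replicates + rep))
            run.replicate = rep
            runs.append(run)
    return runs


def simulate_cell_number_series(
        params: SimulationParams, antigen: str = "titin",
        serum_id: str = "serum",
        cell_counts: tuple[int, ...] = (1_000_000, 3_000_000, 5_000_000, 10_000_000),
        replicates: int = 1) -> list[AssayRun]:
    """One assay per (cell count, replicate); event counts scale linearly
    with the nominal cell number (``events_per_million`` events stand in
    for 10^6 cells).  Defaults follow the bench validation design
    (1, 3, 5 and 10 million cells)."""
    if not cell_counts:
        raise ParameterError("cell_counts must be non-empty")
    if any(c <= 0 for c in cell_counts):
        raise ParameterError("cell_counts must be positive")
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    runs = []
    for i, count in enumerate(cell_counts):
        n_events = int(round(count / 1e6 * params.events_per_million))
        for rep in range(replicates):
            run = simulate_assay(
                replace(params, n_events=n_events, cell_count_nominal=int(count)),
                antigen, serum_id, stream_base=4 * (i * replicates + rep))
            run.replicate = rep
            runs.append(run)
    return runs


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class GroupSpec:
    """One study group: size, per-antigen seropositivity prevalence and the
    titre distribution of the positives (log-normal on the titre scale)."""

    name: str
    n_patients: int
    prevalence: dict  # antigen -> probability in [0, 1]
    titer_log_mean: float = math.log(10.0)
    titer_log_sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ParameterError("n_patients must be >= 0")
        for antigen, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ParameterError(
                    f"prevalence for {antigen!r} outside [0, 1]: {p}")


@dataclass
class CohortSimulation:
    runs: list          # AssayRun per (patient, antigen)
    truth: pd.DataFrame  # patient_id, group, antigen, true_serostatus, titer
    manifest: SampleManifest | None = None


def simulate_cohort(group_specs: list[GroupSpec], params: SimulationParams,
                    outdir: str | Path | None = None,
                    file_format: str = "csv") -> CohortSimulation:
    """Simulate a cohort of patients, one assay per patient x antigen.

    Per-patient serostatus is Bernoulli(prevalence); positives draw their
    titre from the group's log-normal.  With ``outdir`` set, event tables,
    a sample manifest and the truth table are written to disk; otherwise
    everything stays in memory.
    """
    runs: list[AssayRun] = []
    truth_rows = []
    patient_index = 0
    for g, spec in enumerate(group_specs):
        antigens = sorted(spec.prevalence)
        for p in range(spec.n_patients):
            patient_id = f"{spec.name}_{p + 1:03d}"
            status_rng = _rng(params.seed, 1, patient_index)
            for a, antigen in enumerate(antigens):
                positive = bool(status_rng.random() < spec.prevalence[antigen])
                titer = float(status_rng.lognormal(
                    spec.titer_log_mean, spec.titer_log_sigma)) if positive else 0.0
                run = simulate_assay(
                    replace(params, antibody_titer=titer),
                    antigen, patient_id,
                    stream_base=4 * (patient_index * len(antigens) + a) + 16)
                runs.append(run)
                truth_rows.append({
                    "patient_id": patient_id, "group": spec.name,
                    "antigen": antigen, "true_serostatus": positive,
                    "titer": titer,
                })
            patient_index += 1

    truth = pd.DataFrame(truth_rows)
    manifest = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = write_cohort_files(runs, outdir, file_format)
        truth.to_csv(outdir / "truth.csv", index=False)
    return CohortSimulation(runs=runs, truth=truth, manifest=manifest)


def write_cohort_files(runs: list[AssayRun], outdir: Path,
                       file_format: str = "csv") -> SampleManifest:
    """Write each run's four samples plus shared controls and the manifest."""
    if file_format not in ("csv", "fcs"):
        raise ParameterError(f"unknown file format {file_format!r}")
    write = write_events_csv if file_format == "csv" else write_fcs
    ext = file_format
    entries: list[ManifestEntry] = []
    written_controls: set[str] = set()
    for i, run in enumerate(runs):
        for key, table in run.samples.items():
            role = "test" if key.startswith("test") else "no_serum_with_secondary"
            if role == "no_serum_with_secondary":
                fname = f"{table.sample_id}.{ext}"
                if fname in written_controls:
                    continue
                written_controls.add(fname)
            else:
                fname = f"run{i:04d}_{table.sample_id}.{ext}"
            write(table, outdir / fname)
            entries.append(ManifestEntry(
                path=fname, sample_id=table.sample_id, role=role,
                cell_line=table.cell_line, antigen=table.antigen,
                serum_id=table.serum_id, dilution=table.dilution,
            ))
    manifest = SampleManifest(entries)
    save_manifest(manifest, outdir / "manifest.yaml")
    return manifest
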