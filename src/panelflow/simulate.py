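"""Synthetic fixtures with the statistical structure the pipeline assumes.

Three generators, each emitting a machine-readable truth table so oracle
tests never re-derive ground truth from the pipeline itself:

* :func:`simulate_chromatograms` — Gaussian MRM peaks with per-sample RT
  jitter, multiplicative injection-order drift, additive noise, blanks and
  a known quantifier/qualifier area ratio.  Gaussian shapes keep the true
  areas closed-form (A·σ·√(2π)).
* :func:`simulate_cohort` — a four-group cohort (HC/PD/iRBD/OND) of
  protein ratios: multivariate Gaussian on the log scale (MS ratio data
  are right-skewed), informative proteins shifted by a standardized effect
  in a declared direction, exchangeable correlation within the up- and
  down-regulated blocks, MCAR missingness, and clinical scores driven by a
  latent severity shared with the informative proteins.
* :func:`simulate_longitudinal` — per-subject random-intercept/slope
  trajectories over irregular visits for the growth models.

Default cohort sizes (HC 36, PD 99, iRBD 18, OND 41) and the default
8-protein informative set (GRN, MASP2, HSPA5, PTGDS, ICAM1, C3, DKK3,
SERPING1) mirror the study the pipeline targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromio import AreaMatrix, ChromatogramTrace
from .panel import PanelConfig, TransitionDef, TransitionRole
from .qc import FeatureTable

__all__ = [
    "ChromatogramSimSpec",
    "CohortSimSpec",
    "make_demo_panel",
    "simulate_chromatograms",
    "simulate_cohort",
    "simulate_longitudinal",
]

PANEL_PROTEINS_8 = ["GRN", "MASP2", "HSPA5", "PTGDS", "ICAM1", "C3", "DKK3", "SERPING1"]
#: directions of the default informative effects (PD vs HC): GRN down, C3 up, ...
DEFAULT_EFFECT_DIRECTIONS = {
    "GRN": -1, "MASP2": -1, "HSPA5": -1, "PTGDS": -1,
    "ICAM1": +1, "C3": +1, "DKK3": -1, "SERPING1": +1,
}
DEFAULT_GROUP_SIZES = {"HC": 36, "PD": 99, "iRBD": 18, "OND": 41}

_AA = "ACDEFGHIKLMNPQRSTVWY"


def make_demo_panel(
    n_proteins: int = 6,
    peptides_per_protein: int = 1,
    include_standards: bool = True,
    seed: int = 0,
) -> PanelConfig:
    """A small synthetic transition panel (demo assay design).

    ``n_proteins`` analyte proteins plus, when requested, the ALDOA/GSTO1
    internal standards and the ENO1 digestion standard.  Peptide sequences
    and m/z values are synthetic but structurally valid.
    """
    rng = np.random.default_rng(seed)
    proteins = [f"PROT{i + 1}" for i in range(n_proteins)]
    if n_proteins <= len(PANEL_PROTEINS_8):
        proteins = PANEL_PROTEINS_8[:n_proteins]
    if include_standards:
        proteins = proteins + ["ALDOA", "GSTO1", "ENO1"]
    transitions = []
    for prot in proteins:
        for j in range(peptides_per_protein):
            length = int(rng.integers(8, 16))
            pep = "".join(rng.choice(list(_AA), size=length))
            prec = float(np.round(rng.uniform(400, 900), 3))
            for role, prod_off in ((TransitionRole.QUANTIFIER, 150.0), (TransitionRole.QUALIFIER, 220.0)):
                transitions.append(
                    TransitionDef(
                        protein_id=prot,
                        peptide_seq=pep,
                        precursor_mz=prec,
                        product_mz=float(np.round(prec + prod_off + j, 3)),
                        role=role,
                        collision_energy=float(np.round(rng.uniform(15, 40), 1)),
                    )
                )
    return PanelConfig(
        transitions=transitions,
        internal_standards=["ALDOA", "GSTO1"] if include_standards else [],
        digestion_standard="ENO1" if include_standards else "",
    )


@dataclass
class ChromatogramSimSpec:
    """Acquisition model for synthetic MRM chromatograms.

    Defaults give ≥ 12 acquisition points per ±2σ peak (0.05 min σ at a
    0.005 min sampling interval → 40 points), matching the acquisition
    target of the assay the pipeline emulates.
    """

    panel: PanelConfig
    n_samples: int = 10
    n_blanks: int = 2
    peak_sigma: float = 0.05  # minutes
    amplitude_meanlog: float = np.log(5e4)
    amplitude_sdlog: float = 0.4
    rt_jitter_sd: float = 0.0  # minutes
    noise_sd: float = 0.0  # fraction of each peak's amplitude
    drift_coefficient: float = 0.0  # fractional response change across the run
    blank_level: float = 0.0  # blank signal as a fraction of mean amplitude
    sampling_interval: float = 0.005  # minutes
    quantqual_ratio: float = 5.0
    rt_min: float = 1.0
    rt_max: float = 9.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("peak_sigma", "sampling_interval", "quantqual_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        points_per_peak = 4 * self.peak_sigma / self.sampling_interval
        if points_per_peak < 12:
            raise ValueError(
                f"sampling_interval gives only {points_per_peak:.0f} points per ±2σ peak (< 12)"
            )


def simulate_chromatograms(
    spec: ChromatogramSimSpec,
) -> tuple[list[ChromatogramTrace], pd.DataFrame, pd.DataFrame]:
    """Generate traces, a run sheet, and the truth table.

    Study samples carry Gaussian peaks per transition with lognormal
    amplitudes, per-sample RT jitter (one rigid shift per sample),
    multiplicative drift over injection order, and additive Gaussian noise
    floored at 0.  Qualifier peaks are the quantifier scaled by
    1/quantqual_ratio.  Blank injections carry ``blank_level`` × mean
    amplitude peaks (plus noise).  Deterministic given ``spec.seed``.

    Returns ``(traces, runsheet, truth)``; truth has one row per
    (sample, transition) with the true area and apex RT.
    """
    rng = np.random.default_rng(spec.seed)
    panel = spec.panel
    peptides = panel.peptides
    # one true RT per peptide, spread over the gradient, shared by both roles
    rts = np.linspace(spec.rt_min + 0.5, spec.rt_max - 0.5, len(peptides))
    peptide_rt = dict(zip(peptides, rts))
    base_amp = {
        pep: float(rng.lognormal(spec.amplitude_meanlog, spec.amplitude_sdlog))
        for pep in peptides
    }
    mean_amp = float(np.mean(list(base_amp.values())))

    sample_ids = [f"S{i + 1:03d}" for i in range(spec.n_samples)]
    blank_ids = [f"BLANK{i + 1}" for i in range(spec.n_blanks)]
    all_ids = sample_ids + blank_ids
    order = rng.permutation(len(all_ids)) + 1
    runsheet = pd.DataFrame(
        {
            "sample_id": all_ids,
            "injection_order": order,
            "role": ["study"] * len(sample_ids) + ["blank"] * len(blank_ids),
            "group": [None] * len(all_ids),
            "calibration_level": [None] * len(all_ids),
        }
    )
    order_map = dict(zip(all_ids, order))
    n_run = len(all_ids)

    jitter = {s: float(rng.normal(0.0, spec.rt_jitter_sd)) if spec.rt_jitter_sd else 0.0
              for s in all_ids}
    times = np.arange(spec.rt_min, spec.rt_max + spec.sampling_interval / 2,
                      spec.sampling_interval)

    traces: list[ChromatogramTrace] = []
    truth_rows = []
    for s in all_ids:
        is_blank = s in blank_ids
        drift = 1.0 + spec.drift_coefficient * (order_map[s] - 1) / max(n_run - 1, 1)
        for t in panel.transitions:
            pep = t.peptide_seq
            amp = base_amp[pep] * drift
            if t.role == TransitionRole.QUALIFIER:
                amp /= spec.quantqual_ratio
            if is_blank:
                amp = spec.blank_level * mean_amp * drift
                if t.role == TransitionRole.QUALIFIER:
                    amp /= spec.quantqual_ratio
            rt = peptide_rt[pep] + jitter[s]
            signal = amp * np.exp(-0.5 * ((times - rt) / spec.peak_sigma) ** 2)
            if spec.noise_sd > 0:
                ref_amp = max(amp, spec.blank_level * mean_amp, 1.0)
                signal = signal + rng.normal(0.0, spec.noise_sd * ref_amp, times.size)
            signal = np.clip(signal, 0.0, None)
            traces.append(ChromatogramTrace(s, t.key, times.copy(), signal))
            truth_rows.append(
                {
                    "sample_id": s,
                    "transition_key": t.key,
                    "peptide": pep,
                    "role": t.role.value,
                    "true_area": amp * spec.peak_sigma * np.sqrt(2 * np.pi),
                    "true_rt": rt,
                    "true_amplitude": amp,
                    "rt_shift_truth": jitter[s],
                    "drift_factor": drift,
                }
            )
    return traces, runsheet, pd.DataFrame(truth_rows)


@dataclass
class CohortSimSpec:
    """Cohort model for the sample × protein feature table.

    Protein ratios are lognormal.  Per protein the within-group log-value
    SD is ``sdlog`` (0.3 ≈ a 30% coefficient of variation, typical of
    internal-standard-normalized plasma ratios).  Informative proteins are
    shifted by exactly ``effect_size`` log-scale standardized units in
    their declared direction for the affected groups (PD fully; iRBD at
    ``irbd_attenuation`` of the PD shift, emulating a prodromal
    intermediate; OND unshifted, acting as a specificity control).
    Within-group correlation of informative proteins decomposes into a
    shared latent-severity factor (fraction ``severity_loading²`` of the
    variance) plus an exchangeable residual correlation ``block_rho``
    within the up- and the down-regulated block; UPDRS-like and MMSE-like
    clinical scores are monotone in the same latent severity.
    """

    n_per_group: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_proteins: int = 32
    informative_proteins: list[str] = field(default_factory=lambda: list(PANEL_PROTEINS_8))
    effect_size: float = 2.0  # log-scale standardized mean difference, PD vs HC
    effect_directions: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_DIRECTIONS)
    )
    sdlog: float = 0.3
    block_rho: float = 0.3  # residual exchangeable correlation within a block
    irbd_attenuation: float = 0.8
    missing_rate: float = 0.0
    severity_loading: float = 0.4  # sqrt of the shared-severity variance fraction
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.n_per_group.values()):
            raise ValueError("group counts must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not -0.99 < self.block_rho < 0.99:
            raise ValueError("block_rho out of range")
        if not 0 <= self.severity_loading < 1:
            raise ValueError("severity_loading must lie in [0, 1)")
        if self.sdlog <= 0:
            raise ValueError("sdlog must be positive")
        unknown = set(self.effect_directions) - set(self.informative_proteins)
        if unknown:
            raise ValueError(f"directions given for non-informative proteins: {unknown}")


def _protein_names(spec: CohortSimSpec) -> list[str]:
    names = list(spec.informative_proteins)
    i = 1
    while len(names) < spec.n_proteins:
        names.append(f"NULL{i:02d}")
        i += 1
    return names[: spec.n_proteins]


def simulate_cohort(spec: CohortSimSpec) -> tuple[FeatureTable, pd.DataFrame]:
    """Generate the cohort feature table and its truth table.

    Returns ``(table, truth)``; truth lists per protein whether it is
    informative, its standardized log-scale effect size and direction.
    """
    rng = np.random.default_rng(spec.seed)
    proteins = _protein_names(spec)
    directions = {p: spec.effect_directions.get(p, 1) for p in proteins}
    informative = set(spec.informative_proteins) & set(proteins)

    # residual exchangeable correlation within the up- and down-regulated blocks
    cov = np.eye(len(proteins))
    for block_sign in (+1, -1):
        block = [i for i, p in enumerate(proteins)
                 if p in informative and directions[p] == block_sign]
        for a in block:
            for b in block:
                if a != b:
                    cov[a, b] = spec.block_rho
    eig = np.linalg.eigvalsh(cov)
    if eig[0] <= 0:
        raise ValueError("block correlation structure is not positive definite")
    chol = np.linalg.cholesky(cov)

    lam = spec.severity_loading
    resid_scale = np.sqrt(1.0 - lam**2)
    group_shift = {"HC": 0.0, "PD": 1.0, "iRBD": spec.irbd_attenuation, "OND": 0.0}
    rows, meta_rows = [], []
    for group, n in spec.n_per_group.items():
        shift = group_shift.get(group, 0.0)
        for k in range(n):
            # latent severity: centered on the group shift; its standardized
            # residual is the factor shared by the informative proteins
            sev_resid = rng.standard_normal()
            severity = shift + 0.5 * sev_resid
            z = chol @ rng.standard_normal(len(proteins))
            logvals = np.empty(len(proteins))
            for i, p in enumerate(proteins):
                if p in informative:
                    unit = lam * sev_resid + resid_scale * z[i]
                    logvals[i] = spec.sdlog * (
                        directions[p] * spec.effect_size * shift + unit
                    )
                else:
                    logvals[i] = spec.sdlog * z[i]
            rows.append(np.exp(logvals))
            updrs = max(0.0, 10 + 25 * severity + rng.normal(0, 5))
            mmse = float(np.clip(29 - 2.5 * severity + rng.normal(0, 1), 0, 30))
            meta_rows.append(
                {
                    "group": group,
                    "age": float(np.clip(rng.normal(66, 8), 40, 90)),
                    "sex": rng.choice(["F", "M"]),
                    "UPDRS_total": updrs,
                    "MMSE": mmse,
                    "severity_truth": severity,
                }
            )
    index = [f"{g}{i + 1:03d}" for g, n in spec.n_per_group.items() for i in range(n)]
    values = pd.DataFrame(rows, index=index, columns=proteins)
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values = values.mask(mask)
    meta = pd.DataFrame(meta_rows, index=index)
    meta["injection_order"] = rng.permutation(len(index)) + 1

    truth = pd.DataFrame(
        {
            "protein_id": proteins,
            "informative": [p in informative for p in proteins],
            "effect_size": [spec.effect_size if p in informative else 0.0 for p in proteins],
            "direction": [directions[p] if p in informative else 0 for p in proteins],
        }
    )
    return FeatureTable(values, meta), truth


def simulate_longitudinal(
    n_subjects: int = 54,
    visits: tuple[int, int] = (2, 4),
    intercept: float = 1.0,
    slope: float = -0.5,
    intercept_sd: float = 0.5,
    slope_sd: float = 0.2,
    noise_sd: float = 1.0,
    max_years: float = 10.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject random-intercept/slope trajectories over irregular visits.

    Each subject gets a uniform number of visits in ``visits`` (inclusive),
    at time 0 plus irregular follow-ups up to ``max_years``.  Defaults (54
    subjects, 2–4 visits) produce cohort sizes around 146 observations.
    Returns ``(long table, per-subject truth)``.
    """
    if visits[0] < 1 or visits[1] < visits[0]:
        raise ValueError("invalid visits range")
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    for i in range(n_subjects):
        sid = f"RBD{i + 1:03d}"
        b0 = rng.normal(0.0, intercept_sd)
        b1 = rng.normal(0.0, slope_sd)
        n_visits = int(rng.integers(visits[0], visits[1] + 1))
        times = np.concatenate([[0.0], np.sort(rng.uniform(0.5, max_years, n_visits - 1))])
        for t in times:
            y = intercept + slope * t + b0 + b1 * t + rng.normal(0.0, noise_sd)
            rows.append({"subject_id": sid, "years_since_baseline": float(t), "response": y})
        truth_rows.append({"subject_id": sid, "b0": b0, "b1": b1, "n_visits": n_visits})
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(truth_rows)
    truth.attrs["fixed_intercept"] = intercept
    truth.attrs["fixed_slope"] = slope
    return table, truth
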