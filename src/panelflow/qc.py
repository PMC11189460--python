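"""QC and normalization: raw transition areas → analysis-ready protein table.

The chain mirrors a targeted-proteomics quality workflow and must run in
this order:

1. ``digestion_gate``      — drop samples without a yeast-ENO1 signal
                             (failed digestion);
2. ``quantqual_ratio_check`` — flag cells whose quantifier/qualifier area
                             ratio deviates from the peptide's median ratio
                             (wrong peak integrated);
3. ``subtract_blank``      — subtract mean blank signal per transition,
                             floored at zero;
4. ``normalize_to_is``     — divide quantifier areas by an internal-standard
                             protein's area to get relative concentrations,
                             then average peptides per protein;
5. ``correct_drift``       — divide out a LOWESS trend over injection order;
6. ``mask_outliers``       — mask values beyond k median absolute deviations
                             from each protein's median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .chromio import AreaMatrix, SampleRole
from .panel import PanelConfig, PipelineParams, TransitionRole

__all__ = [
    "FeatureTable",
    "QcConfigError",
    "digestion_gate",
    "quantqual_ratio_check",
    "subtract_blank",
    "normalize_to_is",
    "correct_drift",
    "mask_outliers",
    "run_qc_chain",
    "detection_rate_filter",
]

GROUPS = ("HC", "PD", "iRBD", "OND")


class QcConfigError(ValueError):
    pass


@dataclass
class FeatureTable:
    """Samples × proteins relative concentrations with clinical metadata.

    ``values`` holds internal-standard-normalized ratios (dimensionless,
    non-negative, NaN = missing); ``metadata`` is indexed by sample and may
    carry group, age, sex, injection_order, subject_id, years_since_baseline
    and clinical scores (UPDRS, MMSE, ...).
    """

    values: pd.DataFrame
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate sample ids in FeatureTable")
        self.values = self.values.astype(float)
        if (self.values.to_numpy() < 0).any():
            raise ValueError("FeatureTable values must be non-negative or missing")
        if not self.metadata.empty:
            self.metadata = self.metadata.reindex(self.values.index)
            if "group" in self.metadata:
                bad = set(self.metadata["group"].dropna()) - set(GROUPS)
                if bad:
                    raise ValueError(f"unknown groups in metadata: {sorted(bad)}")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def proteins(self) -> list[str]:
        return list(self.values.columns)

    def group_values(self, protein: str, group: str) -> np.ndarray:
        sel = self.metadata["group"] == group
        return self.values.loc[sel, protein].dropna().to_numpy()

    def subset_groups(self, groups: list[str]) -> "FeatureTable":
        sel = self.metadata["group"].isin(groups)
        return FeatureTable(self.values.loc[sel].copy(), self.metadata.loc[sel].copy())


def _quantifier_columns(panel: PanelConfig, protein: str) -> list[str]:
    return [
        t.key
        for t in panel.transitions
        if t.protein_id == protein and t.role == TransitionRole.QUANTIFIER
    ]


def digestion_gate(areas: AreaMatrix, panel: PanelConfig) -> tuple[AreaMatrix, pd.DataFrame]:
    """Exclude samples with no digestion-standard (ENO1) signal.

    A missing or zero quantifier area for the spiked yeast enolase means the
    tryptic digestion failed for that sample; every such sample is removed.
    Returns the filtered matrix and an exclusion report.
    """
    std = panel.digestion_standard
    cols = _quantifier_columns(panel, std) if std else []
    cols = [c for c in cols if c in areas.values.columns]
    if not cols:
        raise QcConfigError(
            f"digestion standard {std!r} has no quantifier column in the area matrix"
        )
    signal = areas.values[cols].sum(axis=1, min_count=1)
    failed = signal.isna() | (signal <= 0)
    report = pd.DataFrame(
        {"sample_id": areas.values.index, "excluded": failed.to_numpy()}
    )
    if failed.all():
        warnings.warn("digestion gate excluded every sample", stacklevel=2)
    kept = areas.subset_samples(list(areas.values.index[~failed]))
    return kept, report


def quantqual_ratio_check(
    areas: AreaMatrix,
    panel: PanelConfig,
    tolerance: float = 0.30,
) -> pd.DataFrame:
    """Flag (sample, peptide) cells whose quant/qual area ratio is off.

    For each peptide the quantifier/qualifier area ratio should be a
    property of the transition chemistry, constant across samples; a cell
    whose ratio deviates from the peptide's cross-sample median by more
    than ``tolerance`` (relative) most likely had the wrong peak
    integrated and is flagged (True) so the quantifier is treated as
    missing downstream.  Undefined ratios (qualifier area 0) are flagged.
    """
    flags = pd.DataFrame(False, index=areas.values.index, columns=panel.peptides)
    for pep in panel.peptides:
        qk = panel.transition(pep, TransitionRole.QUANTIFIER).key
        lk = panel.transition(pep, TransitionRole.QUALIFIER).key
        if qk not in areas.values.columns or lk not in areas.values.columns:
            continue
        quant = areas.values[qk]
        qual = areas.values[lk]
        ratio = quant / qual.replace(0.0, np.nan)
        med = ratio.median()
        undefined = quant.notna() & (qual.isna() | (qual == 0))
        if np.isfinite(med) and med != 0:
            off = (ratio - med).abs() / abs(med) > tolerance
            flags[pep] = off.fillna(False) | undefined
        else:
            flags[pep] = undefined
    return flags


def subtract_blank(areas: AreaMatrix) -> tuple[AreaMatrix, pd.DataFrame]:
    """Subtract the mean blank-injection signal per transition.

    Only transitions with a nonzero mean blank area are corrected; the
    corrected value floors at zero (a floor event is reported, not left
    negative).  With no blank injections present this is a warned no-op.
    """
    blanks = areas.role_samples(SampleRole.BLANK)
    if not blanks:
        warnings.warn("no blank samples in run sheet; blank subtraction skipped", stacklevel=2)
        return areas, pd.DataFrame()
    blank_mean = areas.values.loc[blanks].mean()
    corrected = areas.values.copy()
    floor_cells = []
    for col, b in blank_mean.items():
        if not np.isfinite(b) or b == 0:
            continue
        newvals = corrected[col] - b
        floored = newvals < 0
        for s in corrected.index[floored & corrected[col].notna()]:
            floor_cells.append({"sample_id": s, "transition_key": col})
        corrected[col] = newvals.clip(lower=0.0)
    report = pd.DataFrame(floor_cells, columns=["sample_id", "transition_key"])
    return AreaMatrix(corrected, areas.runsheet), report


def normalize_to_is(
    areas: AreaMatrix,
    panel: PanelConfig,
    standard: str | None = None,
    ratio_flags: pd.DataFrame | None = None,
    drop_standards: bool = True,
) -> FeatureTable:
    """Internal-standard normalization: quantifier areas → relative ratios.

    Each sample's quantifier areas are divided by that sample's
    internal-standard signal (ALDOA by default, GSTO1 as fallback), which
    cancels per-sample global factors (injection volume, global response).
    Peptide ratios are then averaged per protein.  A sample with a zero or
    missing standard gets an all-missing row.
    """
    if standard is None:
        for cand in panel.internal_standards:
            if _quantifier_columns(panel, cand):
                standard = cand
                break
    if standard not in panel.internal_standards:
        raise QcConfigError(
            f"standard {standard!r} is not among panel internal standards "
            f"{panel.internal_standards}"
        )
    std_cols = [c for c in _quantifier_columns(panel, standard) if c in areas.values.columns]
    if not std_cols:
        raise QcConfigError(f"no quantifier columns for standard {standard!r}")
    is_signal = areas.values[std_cols].mean(axis=1)
    is_signal = is_signal.where(is_signal > 0)

    quant = areas.values.copy()
    if ratio_flags is not None:
        for pep in ratio_flags.columns:
            try:
                qk = panel.transition(pep, TransitionRole.QUANTIFIER).key
            except KeyError:
                continue
            if qk in quant.columns:
                quant.loc[ratio_flags[pep].reindex(quant.index, fill_value=False), qk] = np.nan

    skip = {standard, panel.digestion_standard} if drop_standards else set()
    protein_cols = {}
    for prot in panel.proteins:
        if prot in skip:
            continue
        cols = [c for c in _quantifier_columns(panel, prot) if c in quant.columns]
        if not cols:
            continue
        ratios = quant[cols].div(is_signal, axis=0)
        protein_cols[prot] = ratios.mean(axis=1)
    values = pd.DataFrame(protein_cols)

    meta = pd.DataFrame(index=values.index)
    if not areas.runsheet.empty:
        meta = areas.runsheet.set_index("sample_id").reindex(values.index)
    return FeatureTable(values, meta)


def correct_drift(
    table: FeatureTable, frac: float = 0.5, min_points: int = 8
) -> FeatureTable:
    """Remove slow instrument-response drift over injection order.

    Per protein, a LOWESS curve of value versus injection order (span
    ``frac``) estimates the multiplicative drift trend; values are divided
    by the trend and rescaled so the protein's mean is preserved exactly.
    Proteins with fewer than ``min_points`` observations are left
    uncorrected with a warning.
    """
    if "injection_order" not in table.metadata.columns:
        raise QcConfigError("correct_drift requires injection_order metadata")
    order = table.metadata["injection_order"].astype(float)
    corrected = table.values.copy()
    for prot in table.proteins:
        y = table.values[prot]
        ok = y.notna() & order.notna()
        if ok.sum() < min_points:
            warnings.warn(f"{prot}: too few points for drift correction", stacklevel=2)
            continue
        fitted = _sm_lowess(
            y[ok].to_numpy(), order[ok].to_numpy(), frac=frac, it=0, return_sorted=False
        )
        if np.any(fitted <= 0):
            warnings.warn(f"{prot}: non-positive drift trend; left uncorrected", stacklevel=2)
            continue
        new = y[ok].to_numpy() / fitted * float(np.mean(fitted))
        # exact per-protein mean preservation
        new *= float(np.mean(y[ok])) / float(np.mean(new))
        corrected.loc[ok, prot] = new
    return FeatureTable(corrected, table.metadata.copy())


def mask_outliers(
    table: FeatureTable, k: float = 10.0, min_points: int = 3
) -> tuple[FeatureTable, pd.DataFrame]:
    """Mask values beyond ``k`` median absolute deviations from the median.

    The MAD here is unscaled (median of |x − median|, no 1.4826 factor), so
    ``k = 10`` reads literally as ten median deviations.  Only the value is
    masked, never the whole sample.  A protein with MAD 0 is left untouched
    with a warning (the rule is undefined there).
    """
    masked_cells = []
    out = table.values.copy()
    for prot in table.proteins:
        x = table.values[prot]
        obs = x.dropna()
        if len(obs) < min_points:
            continue
        med = float(obs.median())
        mad = float((obs - med).abs().median())
        if mad == 0:
            warnings.warn(f"{prot}: MAD is zero, outlier rule skipped", stacklevel=2)
            continue
        bad = (x - med).abs() > k * mad
        for s in x.index[bad.fillna(False)]:
            masked_cells.append({"sample_id": s, "protein_id": prot, "value": x[s]})
        out.loc[bad.fillna(False), prot] = np.nan
    report = pd.DataFrame(masked_cells, columns=["sample_id", "protein_id", "value"])
    return FeatureTable(out, table.metadata.copy()), report


def detection_rate_filter(
    table: FeatureTable, min_rate: float = 0.80
) -> tuple[FeatureTable, list[str]]:
    """Keep proteins quantified in at least ``min_rate`` of study samples.

    This operationalizes "consistently and reliably detected"; the default
    80% threshold is a tunable parameter of this toolkit, not a claim about
    the original assay's criterion.
    """
    if "role" in table.metadata.columns:
        study = table.metadata["role"] == SampleRole.STUDY
        vals = table.values.loc[study] if study.any() else table.values
    else:
        vals = table.values
    rate = vals.notna().mean()
    dropped = [p for p in table.proteins if rate[p] < min_rate]
    kept = [p for p in table.proteins if rate[p] >= min_rate]
    return FeatureTable(table.values[kept].copy(), table.metadata.copy()), dropped


def run_qc_chain(
    areas: AreaMatrix,
    panel: PanelConfig,
    params: PipelineParams | None = None,
    standard: str | None = None,
    blank_subtraction: bool = True,
    drift_correction: bool = True,
    outlier_masking: bool = True,
) -> tuple[FeatureTable, dict[str, pd.DataFrame]]:
    """Run the full QC chain in its canonical order; returns table + reports."""
    params = params or PipelineParams()
    reports: dict[str, pd.DataFrame] = {}
    gated, reports["digestion_gate"] = digestion_gate(areas, panel)
    flags = quantqual_ratio_check(gated, panel, params.ratio_tolerance)
    reports["ratio_flags"] = flags
    if blank_subtraction:
        gated, reports["blank_floor"] = subtract_blank(gated)
    table = normalize_to_is(gated, panel, standard=standard, ratio_flags=flags)
    if "role" in table.metadata.columns:
        keep = table.metadata["role"].isin([SampleRole.STUDY, SampleRole.POOLED_QC])
        table = FeatureTable(table.values.loc[keep].copy(), table.metadata.loc[keep].copy())
    if drift_correction:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = correct_drift(table, params.drift_frac)
    if outlier_masking:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table, reports["outliers"] = mask_outliers(table, params.outlier_k)
    return table, reports
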