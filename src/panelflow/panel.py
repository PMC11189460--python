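"""Targeted-assay design: proteins, peptides, and their MRM transitions.

A multiple-reaction-monitoring (MRM) assay monitors, for every peptide, a
pair of precursor→product ion transitions: a *quantifier* used for relative
quantification and a *qualifier* whose area ratio to the quantifier confirms
that the correct peak was integrated.  The panel additionally declares which
proteins act as internal standards (signal normalization) and which spiked
protein gates digestion efficiency.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "TransitionRole",
    "TransitionDef",
    "PanelConfig",
    "PipelineParams",
    "PanelFormatError",
    "PanelValidationError",
    "load_panel",
    "write_panel",
    "transition_key",
]

#: peptide lengths outside this range trigger a warning (soft constraint)
PEPTIDE_LENGTH_RANGE = (7, 20)

#: m/z agreement tolerance (Th) used when deduplicating transition rows
MZ_TOLERANCE = 1e-4


class PanelFormatError(ValueError):
    """The panel file cannot be parsed into transition rows."""


class PanelValidationError(ValueError):
    """The parsed transitions violate panel invariants."""


class TransitionRole(str, enum.Enum):
    QUANTIFIER = "quantifier"
    QUALIFIER = "qualifier"


@dataclass(frozen=True)
class TransitionDef:
    """One precursor/product m/z pair monitored for a peptide."""

    protein_id: str
    peptide_seq: str
    precursor_mz: float
    product_mz: float
    role: TransitionRole
    collision_energy: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "role", TransitionRole(self.role))
        if self.precursor_mz <= 0 or self.product_mz <= 0:
            raise PanelValidationError(
                f"non-positive m/z for {self.protein_id}/{self.peptide_seq}"
            )
        lo, hi = PEPTIDE_LENGTH_RANGE
        if not lo <= len(self.peptide_seq) <= hi:
            warnings.warn(
                f"peptide {self.peptide_seq!r} ({self.protein_id}) has length "
                f"{len(self.peptide_seq)}, outside the preferred [{lo}, {hi}] range",
                stacklevel=2,
            )

    @property
    def key(self) -> str:
        return transition_key(self)


def transition_key(t: TransitionDef) -> str:
    """Deterministic unique key for a transition.

    ``peptide_seq|precursor_mz|product_mz|role`` with m/z printed via
    ``repr`` so the key is stable across runs and round-trips.
    """
    return f"{t.peptide_seq}|{t.precursor_mz:g}|{t.product_mz:g}|{t.role.value}"


@dataclass
class PanelConfig:
    """A validated transition panel.

    Invariants: every peptide carries exactly one quantifier and one
    qualifier row, hence ``len(transitions) == 2 * n_peptides``; the
    internal standards and the digestion standard are themselves present
    in the panel.
    """

    transitions: list[TransitionDef]
    internal_standards: list[str] = field(default_factory=lambda: ["ALDOA", "GSTO1"])
    digestion_standard: str = "ENO1"
    heavy_spikes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        seen: dict[tuple[str, TransitionRole], TransitionDef] = {}
        for t in self.transitions:
            k = (t.peptide_seq, t.role)
            prev = seen.get(k)
            if prev is not None:
                same_mz = (
                    abs(prev.precursor_mz - t.precursor_mz) <= MZ_TOLERANCE
                    and abs(prev.product_mz - t.product_mz) <= MZ_TOLERANCE
                )
                kind = "duplicate" if same_mz else "conflicting"
                raise PanelValidationError(
                    f"{kind} {t.role.value} rows for peptide {t.peptide_seq!r}"
                )
            seen[k] = t
        bad = [
            pep
            for pep in self.peptides
            if {t.role for t in self.transitions if t.peptide_seq == pep}
            != {TransitionRole.QUANTIFIER, TransitionRole.QUALIFIER}
        ]
        if bad:
            raise PanelValidationError(
                "peptides without exactly one quantifier and one qualifier: "
                + ", ".join(sorted(bad))
            )
        known = set(self.proteins)
        for std in [*self.internal_standards, self.digestion_standard]:
            if std and std not in known:
                raise PanelValidationError(
                    f"declared standard {std!r} has no transitions in the panel"
                )

    @property
    def peptides(self) -> list[str]:
        out: list[str] = []
        for t in self.transitions:
            if t.peptide_seq not in out:
                out.append(t.peptide_seq)
        return out

    @property
    def proteins(self) -> list[str]:
        out: list[str] = []
        for t in self.transitions:
            if t.protein_id not in out:
                out.append(t.protein_id)
        return out

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    def peptides_for(self, protein_id: str) -> list[str]:
        return [p for p in self.peptides if self.protein_of(p) == protein_id]

    def protein_of(self, peptide_seq: str) -> str:
        for t in self.transitions:
            if t.peptide_seq == peptide_seq:
                return t.protein_id
        raise KeyError(peptide_seq)

    def transition(self, peptide_seq: str, role: TransitionRole | str) -> TransitionDef:
        role = TransitionRole(role)
        for t in self.transitions:
            if t.peptide_seq == peptide_seq and t.role == role:
                return t
        raise KeyError((peptide_seq, role))

    def subset(self, proteins: Iterable[str]) -> "PanelConfig":
        keep = set(proteins)
        return PanelConfig(
            transitions=[t for t in self.transitions if t.protein_id in keep],
            internal_standards=[p for p in self.internal_standards if p in keep],
            digestion_standard=self.digestion_standard
            if self.digestion_standard in keep
            else "",
            heavy_spikes=[p for p in self.heavy_spikes if p in keep],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein": [t.protein_id for t in self.transitions],
                "peptide": [t.peptide_seq for t in self.transitions],
                "precursor_mz": [t.precursor_mz for t in self.transitions],
                "product_mz": [t.product_mz for t in self.transitions],
                "role": [t.role.value for t in self.transitions],
                "ce": [t.collision_energy for t in self.transitions],
            }
        )


@dataclass
class PipelineParams:
    """Pipeline-wide constants.

    Defaults encode the published workflow: a 5-point LOWESS smoother, a
    0.5-fraction drift LOWESS, a 10-median-deviation outlier rule, 5% FDR,
    a 70/30 train/test split, stratified 5-fold RFE cross-validation,
    6-split × 40-repetition repeated CV, 1000 label permutations and a
    minimum of 12 points per chromatographic peak.
    """

    smooth_window: int = 5
    drift_frac: float = 0.5
    outlier_k: float = 10.0
    fdr_alpha: float = 0.05
    test_fraction: float = 0.30
    rfe_cv_folds: int = 5
    repeat_cv_splits: int = 6
    repeat_cv_reps: int = 40
    n_permutations: int = 1000
    min_points_per_peak: int = 12
    ratio_tolerance: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("drift_frac", "fdr_alpha", "test_fraction", "ratio_tolerance"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        for name in (
            "smooth_window",
            "rfe_cv_folds",
            "repeat_cv_splits",
            "repeat_cv_reps",
            "n_permutations",
            "min_points_per_peak",
        ):
            v = getattr(self, name)
            if not (isinstance(v, (int,)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v}")
        if self.outlier_k <= 0:
            raise ValueError("outlier_k must be positive")


_REQUIRED_COLUMNS = ["protein", "peptide", "precursor_mz", "product_mz", "role"]


def _read_delimited(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise PanelFormatError(f"empty panel file: {path}") from exc
    if df.empty:
        raise PanelFormatError(f"panel file has no transition rows: {path}")
    return df


def load_panel(
    path: str | Path,
    internal_standards: Sequence[str] | None = None,
    digestion_standard: str = "ENO1",
    heavy_spikes: Sequence[str] | None = None,
) -> PanelConfig:
    """Read a transition panel from CSV/TSV (autodetected by extension).

    Expected header ``protein,peptide,precursor_mz,product_mz,role[,ce]``
    with one transition per row, role ∈ {quantifier, qualifier}.  Standards
    not present in the table are silently dropped from the declared lists so
    panel subsets stay loadable.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = _read_delimited(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise PanelFormatError(f"panel file missing columns: {missing}")
    transitions = []
    for _, row in df.iterrows():
        ce = row.get("ce")
        transitions.append(
            TransitionDef(
                protein_id=str(row["protein"]),
                peptide_seq=str(row["peptide"]),
                precursor_mz=float(row["precursor_mz"]),
                product_mz=float(row["product_mz"]),
                role=TransitionRole(str(row["role"]).strip().lower()),
                collision_energy=None if pd.isna(ce) else float(ce),
            )
        )
    proteins = {t.protein_id for t in transitions}
    if internal_standards is None:
        internal_standards = [p for p in ("ALDOA", "GSTO1") if p in proteins]
    return PanelConfig(
        transitions=transitions,
        internal_standards=[p for p in internal_standards if p in proteins],
        digestion_standard=digestion_standard if digestion_standard in proteins else "",
        heavy_spikes=list(heavy_spikes or []),
    )


def write_panel(panel: PanelConfig, path: str | Path) -> None:
    """Write a panel back to CSV/TSV; inverse of :func:`load_panel`."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    panel.to_frame().to_csv(path, sep=sep, index=False)
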