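"""Run configuration and clinical-table schema declarations."""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

#: days per month used when survival time is recorded in months
DAYS_PER_MONTH = 30.44

#: cell contents treated as missing in clinical tables (TCGA exports use the
#: bracketed markers); their use is logged when encountered
MISSING_MARKERS = ("", "NA", "NaN", "[Not Available]", "[Discrepancy]")


@dataclass(frozen=True)
class CovariateDecl:
    """Declaration of one clinical covariate.

    kind: "categorical" (with a declared reference level) or "continuous".
    """

    name: str
    kind: str = "categorical"
    reference: str | None = None

    def __post_init__(self):
        if self.kind not in ("categorical", "continuous"):
            raise ValueError(f"unknown covariate kind {self.kind!r}")
        if self.kind == "categorical" and self.reference is None:
            raise ValueError(f"categorical covariate {self.name!r} needs a reference level")


@dataclass(frozen=True)
class ClinicalSchema:
    """Column layout of a clinical table.

    The survival triple (os_time, os_event, radiotherapy) is fixed by name;
    everything else is declared per covariate.
    """

    covariates: tuple[CovariateDecl, ...] = ()
    sample_col: str = "sample_id"
    time_col: str = "os_time"
    event_col: str = "os_event"
    rt_col: str = "radiotherapy"

    def covariate(self, name: str) -> CovariateDecl:
        for c in self.covariates:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def covariate_names(self) -> list[str]:
        return [c.name for c in self.covariates]


@dataclass
class RunConfig:
    """Pipeline-wide settings.

    time_unit declares (never infers) the unit of os_time; internal
    day-denominated thresholds such as the minimum-survival rule are
    converted with 1 month = 30.44 days.
    """

    time_unit: str = "days"  # "days" | "months"
    n_imputations: int = 10
    missingness_cap: float = 0.20
    alpha: float = 0.05
    min_survival_days: float = 5.0
    seed: int = 0
    correlation_thresholds: tuple[float, float] = (0.3, 0.8)
    cluster_k: int = 2
    # scenario-rule switches (defaults follow the published rule set)
    require_p_for_ab: bool = False  # also require Wald p < alpha for A/B retention
    reselect_cd: bool = False  # re-run backward selection inside C/D subsets
    bh_correction: bool = False  # Benjamini-Hochberg across the gene panel

    def __post_init__(self):
        if self.time_unit not in ("days", "months"):
            raise ValueError(f"time_unit must be 'days' or 'months', got {self.time_unit!r}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_imputations < 1:
            raise ValueError("n_imputations must be >= 1")
        if not (0 < self.missingness_cap <= 1):
            raise ValueError("missingness_cap must be in (0, 1]")
        self.correlation_thresholds = tuple(self.correlation_thresholds)

    @property
    def min_survival_in_unit(self) -> float:
        """The minimum-survival threshold expressed in the declared unit."""
        if self.time_unit == "days":
            return self.min_survival_days
        return self.min_survival_days / DAYS_PER_MONTH

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()},
                fh,
            )
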