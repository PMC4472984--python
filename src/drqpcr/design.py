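"""Experiment design: factor levels, thresholds, and treatment-label mapping."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import yaml

#: Canonical treatment levels used throughout the package. Free-text labels in
#: input files ("water", "dehydration", ...) are mapped onto these two.
CONTROL = "control"
STRESS = "stress"


class SampleKey(NamedTuple):
    """Identifies one experimental cell (all replicates pooled)."""

    gene_id: str
    cultivar: str
    tissue: str
    treatment: str
    timepoint_h: float


@dataclass(frozen=True)
class ExperimentDesign:
    """Thresholds and factor levels of a two-genotype dehydration screen.

    Parameters
    ----------
    reference_gene:
        Internal-control gene used for ΔCt normalization; must be measured in
        every sample.
    control_treatment_label:
        The raw label (before mapping) of the control treatment.
    tolerant_cultivar, sensitive_cultivar:
        Genotype labels for the cross-cultivar contrast (tolerant/sensitive).
    fold_change_threshold:
        Minimum linear fold change for an up/down or higher/lower call
        (inclusive; default 2.0).
    alpha:
        Significance level for the one-tailed t-test (default 0.05).
    timepoints:
        Stress/control sampling times in hours.
    treatment_labels:
        Mapping from raw treatment labels to {control, stress}.
    """

    reference_gene: str = "IF4a"
    control_treatment_label: str = "water"
    tolerant_cultivar: str = "ILC482"
    sensitive_cultivar: str = "Hashem"
    fold_change_threshold: float = 2.0
    alpha: float = 0.05
    timepoints: Sequence[float] = (2.0, 5.0)
    treatment_labels: Mapping[str, str] = field(
        default_factory=lambda: {
            "water": CONTROL,
            "dehydration": STRESS,
            CONTROL: CONTROL,
            STRESS: STRESS,
        }
    )

    def __post_init__(self) -> None:
        if self.tolerant_cultivar == self.sensitive_cultivar:
            raise ValueError("tolerant and sensitive cultivar must differ")
        if self.fold_change_threshold < 1:
            raise ValueError("fold_change_threshold must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        bad = set(self.treatment_labels.values()) - {CONTROL, STRESS}
        if bad:
            raise ValueError(f"treatment labels must map to control/stress, got {bad}")

    @property
    def log2_threshold(self) -> float:
        import math

        return math.log2(self.fold_change_threshold)

    def map_treatment(self, label: str) -> str:
        try:
            return self.treatment_labels[label]
        except KeyError:
            raise ValueError(
                f"unknown treatment label {label!r}; declare it in treatment_labels"
            ) from None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentDesign":
        raw = yaml.safe_load(Path(path).read_text())
        if "timepoints" in raw:
            raw["timepoints"] = tuple(float(t) for t in raw["timepoints"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "reference_gene": self.reference_gene,
            "control_treatment_label": self.control_treatment_label,
            "tolerant_cultivar": self.tolerant_cultivar,
            "sensitive_cultivar": self.sensitive_cultivar,
            "fold_change_threshold": self.fold_change_threshold,
            "alpha": self.alpha,
            "timepoints": [float(t) for t in self.timepoints],
            "treatment_labels": dict(self.treatment_labels),
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def default_design() -> ExperimentDesign:
    """The packaged default design (two cultivars, two tissues, 2 h / 5 h)."""
    from importlib import resources

    with resources.as_file(
        resources.files("drqpcr") / "data" / "design.yaml"
    ) as p:
        return ExperimentDesign.from_yaml(p)
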