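"""Phase-diagram classification and transition-threshold extraction.

Concentration conditions are classified dispersed vs phase-separated from
their per-ROI index-of-dispersion (IoD) samples: a condition counts as
phase-separated when its median IoD exceeds a reference cutoff, by default
the 99th percentile of the IoD samples of a matched non-separating control
(no numeric cutoff is universal — the reference condition anchors the
decision to the same optics, label and noise floor).  The transition
threshold is then the monotone frontier along a chosen concentration axis:
the smallest concentration from which every higher tested concentration is
also phase-separated.  Thresholds are reported at grid resolution; no
interpolation between tested concentrations is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("condensate_metrics")

__all__ = [
    "PhaseCondition",
    "PhaseDiagram",
    "classify_condition",
    "transition_threshold",
    "build_phase_diagram",
    "REFERENCE_PERCENTILE",
]

#: Percentile of the no-droplet reference IoD distribution used as cutoff.
REFERENCE_PERCENTILE = 99.0

DISPERSED = "dispersed"
PHASE_SEPARATED = "phase_separated"
UNDETERMINED = "undetermined"


@dataclass
class PhaseCondition:
    """One concentration condition with its per-ROI IoD samples.

    ``cin85_uM`` refers to the monomeric concentration.  ``label`` is set
    by :func:`classify_condition` only.
    """

    slp65_uM: float = 0.0
    cin85_uM: float = 0.0
    lipid_mM: float = 0.0
    iod_samples: list[float] = field(default_factory=list)
    label: str | None = None

    def __post_init__(self) -> None:
        if min(self.slp65_uM, self.cin85_uM, self.lipid_mM) < 0:
            raise ValueError("concentrations must be non-negative")
        if any(s < 0 for s in self.iod_samples):
            raise ValueError("IoD samples must be non-negative")


@dataclass
class PhaseDiagram:
    """Conditions ordered along one concentration axis, plus the threshold."""

    conditions: list[PhaseCondition]
    axis: str = "slp65_uM"
    threshold: float | None = None

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                self.axis: [getattr(c, self.axis) for c in self.conditions],
                "median_iod": [float(np.median(c.iod_samples)) for c in self.conditions],
                "label": [c.label for c in self.conditions],
            }
        )


def classify_condition(
    condition: PhaseCondition,
    reference: float | np.ndarray | list[float],
    margin: float = 0.0,
    percentile: float = REFERENCE_PERCENTILE,
) -> str:
    """Label a condition dispersed / phase_separated / undetermined.

    ``reference`` is either a numeric cutoff or the IoD samples of a
    matched no-droplet control, in which case the cutoff is their
    ``percentile``-th percentile.  The condition is phase-separated when
    its median IoD exceeds cutoff + margin, dispersed when it is below
    cutoff − margin, and undetermined inside the band (a median exactly at
    the cutoff is undetermined).

    Raises
    ------
    ValueError
        On fewer than 3 ROI samples.
    """
    if len(condition.iod_samples) < 3:
        raise ValueError("classification needs at least 3 ROI samples")
    if isinstance(reference, (int, float)):
        cutoff = float(reference)
    else:
        cutoff = float(np.percentile(np.asarray(reference, float), percentile))
    median = float(np.median(condition.iod_samples))
    if median > cutoff + margin:
        label = PHASE_SEPARATED
    elif median < cutoff - margin:
        label = DISPERSED
    else:
        label = UNDETERMINED
    condition.label = label
    return label


def transition_threshold(diagram: PhaseDiagram, axis: str | None = None) -> float | None:
    """Smallest concentration from which all higher conditions phase-separate.

    Conditions are sorted ascending on ``axis`` (defaults to the diagram's
    axis).  If the labels are monotone (dispersed below, phase-separated
    above) the frontier is the smallest phase-separated concentration; if
    no condition separates, None.  A non-monotone pattern (a dispersed
    condition above a phase-separated one) logs a warning and the threshold
    is the smallest concentration from which every higher condition is
    phase-separated.

    Raises
    ------
    ValueError
        If any condition is unlabelled.
    """
    axis = axis or diagram.axis
    if any(c.label is None for c in diagram.conditions):
        raise ValueError("all conditions must be labelled before thresholding")
    conds = sorted(diagram.conditions, key=lambda c: getattr(c, axis))
    labels = [c.label for c in conds]
    values = [getattr(c, axis) for c in conds]

    separated = [lab == PHASE_SEPARATED for lab in labels]
    if not any(separated):
        diagram.threshold = None
        return None

    # frontier: smallest index i with separated[i:] all True
    frontier = None
    for i in range(len(conds)):
        if all(separated[i:]):
            frontier = i
            break
    if frontier is None:
        # highest condition is not separated; no consistent frontier exists
        logger.warning(
            "non-monotone phase labels along %s: %s; no consistent frontier",
            axis, labels,
        )
        diagram.threshold = None
        return None
    first_sep = separated.index(True)
    if first_sep < frontier:
        logger.warning(
            "non-monotone phase labels along %s: %s; reporting smallest "
            "consistent frontier %.4g", axis, labels, values[frontier],
        )
    diagram.threshold = float(values[frontier])
    return diagram.threshold


def build_phase_diagram(
    conditions: list[PhaseCondition],
    reference: float | np.ndarray | list[float],
    axis: str = "slp65_uM",
    margin: float = 0.0,
) -> PhaseDiagram:
    """Classify every condition against the reference and extract the threshold."""
    for cond in conditions:
        classify_condition(cond, reference, margin=margin)
    diagram = PhaseDiagram(conditions=sorted(conditions, key=lambda c: getattr(c, axis)),
                           axis=axis)
    transition_threshold(diagram)
    return diagram


def plot_phase_diagram(diagram: PhaseDiagram, path: str | None = None):
    """Median IoD vs concentration, coloured by label; optional save."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = diagram.to_table()
    colors = {DISPERSED: "tab:gray", PHASE_SEPARATED: "tab:blue",
              UNDETERMINED: "tab:orange"}
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for lab, sub in table.groupby("label"):
        ax.scatter(sub[diagram.axis], sub["median_iod"],
                   color=colors.get(lab, "k"), label=lab)
    if diagram.threshold is not None:
        ax.axvline(diagram.threshold, ls="--", color="k",
                   label=f"threshold {diagram.threshold:g}")
    ax.set_xscale("log")
    ax.set_xlabel(diagram.axis.replace("_", " "))
    ax.set_ylabel("median index of dispersion")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
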