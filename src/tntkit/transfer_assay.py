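"""Vesicle-transfer statistics for donor/acceptor co-culture assays.

Transfer is scored as the fraction of acceptor cells containing
donor-derived dye-labelled vesicles.  A parallel conditioned-medium control
measures purely secretion-based transfer; subtracting it isolates
contact-mediated (TNT-route) transfer.  Flow-cytometry runs encode the same
quantity as the double-positive over acceptor-gate event ratio Q2/Q1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class TransferTable:
    """Acceptor-cell counts for one condition and route."""

    n_total: int
    n_positive: int
    condition: str = ""
    route: str = "coculture"  # "coculture" | "secretion-control"

    def __post_init__(self):
        if self.n_total <= 0:
            raise ValueError("total acceptor count must be > 0")
        if not 0 <= self.n_positive <= self.n_total:
            raise ValueError("positives must lie in [0, total]")
        if self.route not in ("coculture", "secretion-control"):
            raise ValueError("route must be 'coculture' or 'secretion-control'")


@dataclass
class FlowCounts:
    """Flow-cytometry gate counts: Q1 acceptor gate, Q2 double positive."""

    q1: int
    q2: int

    def __post_init__(self):
        if self.q1 <= 0:
            raise ValueError("Q1 must be > 0")
        if not 0 <= self.q2 <= self.q1:
            raise ValueError("Q2 must lie in [0, Q1]")


@dataclass
class ContactTransfer:
    """Secretion-corrected contact transfer; negative values are flagged."""

    percent: float
    secretion_exceeds_total: bool


def percent_transfer(table: TransferTable) -> float:
    """100 * positives / total."""
    return 100.0 * table.n_positive / table.n_total


def contact_corrected(total_percent: float, secretion_percent: float) -> ContactTransfer:
    """Contact-mediated transfer: total minus secretion-based transfer.

    Negative results (secretion control exceeding the co-culture total) are
    returned with the ``secretion_exceeds_total`` flag rather than clamped,
    so clamping bias is never silently introduced.
    """
    for v in (total_percent, secretion_percent):
        if not 0.0 <= v <= 100.0:
            raise ValueError("percentages must lie in [0, 100]")
    value = total_percent - secretion_percent
    return ContactTransfer(percent=value, secretion_exceeds_total=value < 0)


def relative_to_control(treatment_percent: float, control_percent: float) -> float:
    """Treatment transfer as a percentage of the control (control = 100%)."""
    if control_percent <= 0:
        raise ValueError("control percentage must be > 0")
    return 100.0 * treatment_percent / control_percent


def relative_to_control_replicates(
    treatment_percents,
    control_percents,
    pooled: bool = False,
) -> float:
    """Relative transfer across replicate pairs.

    Default mode normalizes each treatment replicate by its paired control
    and averages the ratios (matching per-experiment mean +/- SEM
    reporting); ``pooled=True`` instead forms the single ratio of the
    replicate means.  The two estimators differ on unequal replicates.
    """
    t = np.asarray(treatment_percents, dtype=float)
    c = np.asarray(control_percents, dtype=float)
    if t.shape != c.shape or t.size == 0:
        raise ValueError("treatment and control replicates must pair up")
    if np.any(c <= 0):
        raise ValueError("control percentages must be > 0")
    if pooled:
        return 100.0 * t.mean() / c.mean()
    return float(np.mean(100.0 * t / c))


def flow_percent(counts: FlowCounts) -> float:
    """100 * Q2 / Q1 — identical to :func:`percent_transfer` on equal counts."""
    return 100.0 * counts.q2 / counts.q1
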