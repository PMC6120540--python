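"""Signal-homogeneity metrics and method comparison reports.

The two headline quantities, computed on the predicted centre-of-k-space
echo over the whole brain mask, are the coefficient of variation (CoV,
population std / mean) and P10, the proportion of voxels whose prediction
lies within 10% of the spatially constant target signal.  P10 is the more
meaningful of the two because the signal histograms are strongly
non-Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epg import forward_model, target_signal
from .sequence import PulseTrain

__all__ = [
    "QualityReport",
    "coefficient_of_variation",
    "p10",
    "signal_histogram",
    "compare_methods",
]


@dataclass
class QualityReport:
    label: str
    cov: float
    p10: float
    histogram: tuple  # (bin_edges, counts) of I_center / T_center
    n_voxels: int


def coefficient_of_variation(values, mask=None) -> float:
    """Population std divided by mean of the masked values."""
    v = np.asarray(values, dtype=float)
    if mask is not None:
        v = v[np.asarray(mask, dtype=bool)]
    if v.size == 0:
        raise ValueError("no voxels selected")
    mean = v.mean()
    if mean == 0:
        raise ValueError("zero mean signal: CoV undefined")
    return float(v.std() / mean)  # numpy std is the population (n) convention


def p10(values, target: float, mask=None, tolerance: float = 0.1) -> float:
    """Fraction of masked voxels within ``tolerance`` (10%) of the target."""
    if target <= 0:
        raise ValueError("target signal must be positive")
    v = np.asarray(values, dtype=float)
    if mask is not None:
        v = v[np.asarray(mask, dtype=bool)]
    if v.size == 0:
        raise ValueError("no voxels selected")
    return float(np.mean(np.abs(v - target) / target <= tolerance))


def signal_histogram(values, target: float, bins: int = 50, rng=(0.0, 2.0)):
    """Histogram of the relative signal I/T (counts conserve voxel number)."""
    v = np.asarray(values, dtype=float) / target
    counts, edges = np.histogram(np.clip(v, rng[0], rng[1] - 1e-12),
                                 bins=bins, range=rng)
    return edges, counts


def compare_methods(
    fields,
    train: PulseTrain,
    solutions: dict,
    *,
    T1ref: float = 1.5,
    T2ref: float = 0.05,
    center_echo_index: int = None,
) -> pd.DataFrame:
    """Forward-simulate each labelled shim solution and tabulate the metrics.

    ``solutions`` maps labels (e.g. quadrature / static / DSC / universal)
    to ShimSchedules or bare (N_p, N_c) weight matrices.  Returns a
    DataFrame indexed by label with CoV, P10 and the centre-echo statistics;
    the per-method :class:`QualityReport` objects (with histograms) are
    attached as ``df.attrs["reports"]``.
    """
    ce = center_echo_index or train.center_echo_index
    T = target_signal(train, T1ref, T2ref)
    t_center = float(T[ce - 1])
    rows = []
    reports = {}
    predictions = {}
    for label, sol in solutions.items():
        w = getattr(getattr(sol, "schedule", sol), "w", sol)
        pred = forward_model(w, fields, train, T1ref, T2ref)
        I_c = pred.I[:, ce - 1]
        rep = QualityReport(
            label=label,
            cov=coefficient_of_variation(I_c),
            p10=p10(I_c, t_center),
            histogram=signal_histogram(I_c, t_center),
            n_voxels=I_c.size,
        )
        reports[label] = rep
        predictions[label] = I_c
        rows.append(
            {"method": label, "cov": rep.cov, "p10": rep.p10,
             "mean_rel_signal": float(I_c.mean() / t_center),
             "n_voxels": rep.n_voxels}
        )
    df = pd.DataFrame(rows).set_index("method")
    df.attrs["reports"] = reports
    df.attrs["predictions"] = predictions
    df.attrs["target_center"] = t_center
    return df
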