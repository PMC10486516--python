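"""Pairwise McNemar comparison of classifiers on a shared test set.

Two classifiers evaluated on the same test rows are compared through
their discordant predictions only: N_sf counts items the first model gets
right and the second wrong, N_fs the reverse.  The continuity-corrected
z statistic

    z = (|N_sf - N_fs| - 1) / sqrt(N_sf + N_fs)

is treated as a magnitude, with the direction of superiority carried
separately (the model with more discordant wins).  When the counts are
balanced within one the raw statistic is negative; it is clamped to zero
by default — no discordance at all is also defined as z = 0 — and the
signed value is available behind a flag.  z maps to one- and two-tailed
confidence levels through the standard normal CDF.  No multiple-testing
correction is applied across pairs; reports say so in their header.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "McNemarResult",
    "discordant_counts",
    "mcnemar_z",
    "confidence_levels",
    "pairwise_matrix",
    "render_matrix",
    "results_frame",
]

NO_CORRECTION_NOTE = (
    "pairwise McNemar z (continuity-corrected); "
    "no multiple-testing correction applied across pairs"
)


@dataclass
class McNemarResult:
    """One pairwise comparison: discordant counts, z, direction."""

    model_a: str
    model_b: str
    n_sf: int
    n_fs: int
    z: float
    better: str  # name of the model with more discordant wins, or "tie"
    one_tailed_conf: float  # percent
    two_tailed_conf: float  # percent

    def swapped(self) -> "McNemarResult":
        return McNemarResult(
            model_a=self.model_b, model_b=self.model_a,
            n_sf=self.n_fs, n_fs=self.n_sf, z=self.z, better=self.better,
            one_tailed_conf=self.one_tailed_conf,
            two_tailed_conf=self.two_tailed_conf,
        )


def discordant_counts(
    pred_a: Sequence[int], pred_b: Sequence[int], truth: Sequence[int]
) -> tuple[int, int]:
    """(N_sf, N_fs): counts where exactly one model matches the truth."""
    pred_a = np.asarray(pred_a)
    pred_b = np.asarray(pred_b)
    truth = np.asarray(truth)
    if not (len(pred_a) == len(pred_b) == len(truth)):
        raise ValueError("prediction and truth vectors must have equal lengths")
    a_ok = pred_a == truth
    b_ok = pred_b == truth
    n_sf = int(np.sum(a_ok & ~b_ok))
    n_fs = int(np.sum(~a_ok & b_ok))
    return n_sf, n_fs


def mcnemar_z(n_sf: int, n_fs: int, signed: bool = False) -> float:
    """Continuity-corrected McNemar z from the two discordant counts.

    z = (|N_sf - N_fs| - 1) / sqrt(N_sf + N_fs); zero when there is no
    discordance at all.  The raw value is negative when the counts differ
    by at most one: by default it is clamped at 0 (z is a magnitude here,
    direction travels separately); ``signed=True`` returns it raw.
    """
    if n_sf < 0 or n_fs < 0:
        raise ValueError("discordant counts must be nonnegative")
    total = n_sf + n_fs
    if total == 0:
        return 0.0
    raw = (abs(n_sf - n_fs) - 1) / math.sqrt(total)
    if signed:
        return raw
    return max(0.0, raw)


def confidence_levels(z: float) -> tuple[float, float]:
    """(one-tailed, two-tailed) confidence percentages for a z magnitude.

    One-tailed = Phi(z) * 100, two-tailed = (2 Phi(z) - 1) * 100, with
    Phi the standard normal CDF.
    """
    if z < 0:
        raise ValueError("z must be nonnegative")
    phi = float(norm.cdf(z))
    return phi * 100.0, (2.0 * phi - 1.0) * 100.0


def _compare_pair(
    model_a: str, model_b: str,
    pred_a: np.ndarray, pred_b: np.ndarray, truth: np.ndarray,
    signed: bool = False,
) -> McNemarResult:
    n_sf, n_fs = discordant_counts(pred_a, pred_b, truth)
    z = mcnemar_z(n_sf, n_fs, signed=signed)
    if n_sf > n_fs:
        better = model_a
    elif n_fs > n_sf:
        better = model_b
    else:
        better = "tie"
    one_t, two_t = confidence_levels(max(z, 0.0))
    return McNemarResult(
        model_a=model_a, model_b=model_b, n_sf=n_sf, n_fs=n_fs, z=z,
        better=better, one_tailed_conf=one_t, two_tailed_conf=two_t,
    )


def pairwise_matrix(
    predictions: Mapping[str, Sequence[int]],
    truth: Sequence[int],
    signed: bool = False,
) -> list[McNemarResult]:
    """All C(n,2) pairwise comparisons over a model -> predictions map.

    Every prediction vector must be paired with the same truth vector
    (same test rows, same order).  Results come in model-order pairs
    (a before b as given in the mapping).
    """
    models = list(predictions)
    if len(models) < 2:
        raise ValueError("need at least 2 models to compare")
    truth = np.asarray(truth)
    arrays = {}
    for name, pred in predictions.items():
        arr = np.asarray(pred)
        if len(arr) != len(truth):
            raise ValueError(
                f"model {name!r}: {len(arr)} predictions vs {len(truth)} truths"
            )
        arrays[name] = arr
    return [
        _compare_pair(a, b, arrays[a], arrays[b], truth, signed=signed)
        for a, b in itertools.combinations(models, 2)
    ]


def results_frame(results: Sequence[McNemarResult]) -> pd.DataFrame:
    """Serialize pairwise results as a flat table."""
    return pd.DataFrame(
        [
            {
                "model_a": r.model_a, "model_b": r.model_b,
                "N_sf": r.n_sf, "N_fs": r.n_fs, "z": r.z, "better": r.better,
                "one_tailed": r.one_tailed_conf, "two_tailed": r.two_tailed_conf,
            }
            for r in results
        ]
    )


def render_matrix(results: Sequence[McNemarResult]) -> str:
    """Render the upper-triangular z matrix with direction arrows.

    Cell (row, col) shows the z value prefixed by an arrow pointing at
    the better model: '<-' toward the row model, '^' toward the column
    model; plain '0' for a tie.
    """
    order: list[str] = []
    for r in results:
        for name in (r.model_a, r.model_b):
            if name not in order:
                order.append(name)
    by_pair = {(r.model_a, r.model_b): r for r in results}

    def cell(row_model: str, col_model: str) -> str:
        r = by_pair.get((row_model, col_model))
        if r is None:
            r = by_pair[(col_model, row_model)].swapped()
        if r.better == "tie":
            return f"{r.z:.4g}"
        arrow = "<-" if r.better == r.model_a else "^"
        return f"{arrow}{r.z:.4g}"

    width = 10
    lines = ["# " + NO_CORRECTION_NOTE]
    lines.append("".ljust(width) + "".join(m.ljust(width) for m in order[1:]))
    for i, row_model in enumerate(order[:-1]):
        cells = []
        for col_model in order[1:]:
            if order.index(col_model) <= i:
                cells.append("".ljust(width))
            else:
                cells.append(cell(row_model, col_model).ljust(width))
        lines.append(row_model.ljust(width) + "".join(cells))
    return "\n".join(line.rstrip() for line in lines) + "\n"


def save_comparison(
    results: Sequence[McNemarResult], out_dir: str | Path, prefix: str = "mcnemar"
) -> tuple[Path, Path]:
    """Write the pairwise CSV and the rendered text matrix."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{prefix}.csv"
    txt_path = out_dir / f"{prefix}.txt"
    results_frame(results).to_csv(csv_path, index=False)
    txt_path.write_text(render_matrix(results))
    return csv_path, txt_path
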