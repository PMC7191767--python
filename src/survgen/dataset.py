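"""Dataset export and survival-plot rendering.

The generated cohort is written as a flat CSV (comma separator, dot
decimal, UTF-8, mandatory header) so it can be handed directly to any
survival-analysis tool.  With ``include_truth`` the generating ground
truth (LTS/STS membership, survivor flag, numeric-biomarker marking) is
exported alongside, turning the file into a labelled test set.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import ConfigurationError
from .nominalize import km_estimate

__all__ = ["write_dataset", "read_dataset", "export_survival_plot"]


def write_dataset(cohort: Cohort, path, include_truth: bool = False) -> Path:
    """Write the cohort as CSV; returns the path written."""
    path = Path(path)
    frame = cohort.to_frame(include_truth=include_truth)
    frame.to_csv(path, index=False)
    return path


def read_dataset(path) -> pd.DataFrame:
    """Read a previously written cohort CSV."""
    return pd.read_csv(path)


def _is_nominal(series: pd.Series) -> bool:
    return (
        series.dtype == bool
        or series.dtype == object
        or isinstance(series.dtype, pd.CategoricalDtype)
    )


def export_survival_plot(data, stratify_by: str, path) -> Path:
    """Render one Kaplan-Meier curve per stratum of a nominal column.

    ``data`` is a cohort or a data frame with ``time`` and ``event``
    columns.  Numeric columns must be nominalized first; asking for one
    raises an instructive error.  Purely presentational — no analysis
    depends on the rendered pixels.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = data.to_frame(include_truth=True) if isinstance(data, Cohort) else data
    if stratify_by not in frame.columns:
        raise ConfigurationError(f"no column named {stratify_by!r} in the dataset")
    column = frame[stratify_by]
    if not _is_nominal(column):
        raise ConfigurationError(
            f"column {stratify_by!r} is numeric; dichotomize it first with the "
            f"'nominalize' subcommand, then stratify by the resulting groups"
        )
    path = Path(path)
    fig, ax = plt.subplots(figsize=(7, 5))
    for level in sorted(column.unique(), key=str):
        sub = frame[column == level]
        curve = km_estimate(sub["time"].to_numpy(), sub["event"].to_numpy())
        xs = np.concatenate(([0.0], np.repeat(curve.times, 2)))
        ys = np.concatenate((np.repeat(np.concatenate(([1.0], curve.survival)), 2)[:-1],))
        ax.plot(xs, ys, drawstyle="default", label=f"{stratify_by}={level}")
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability S(t)")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path
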