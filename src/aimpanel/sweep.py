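"""Panel-size sweep: accuracy of AIM panels of increasing size.

For every (panel size, multi-In proportion) cell the driver selects a panel,
estimates ancestry proportions from it, and compares them per ancestry with
a reference set of proportions (typically estimated from all genome-wide
markers).  Output is a long-format table — one row per (size, proportion,
ancestry) — from which the classic size-vs-correlation panel chart is a
trivial downstream plot.

Because the greedy selector is deterministic and, with proportion 0,
produces nested panels (a smaller panel is a prefix of a larger one when the
acceptance constraints are unchanged), the sweep simply re-runs selection
per cell; cells that fail are recorded with an error status and the sweep
continues.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .ancestry import estimate_proportions, evaluate_panel
from .datamodel import AncestryMatrix, DataError, FreqTable, GenotypeMatrix, SnpMap, SourceFreqs
from .selection import SelectionConfig, select_aims

logger = logging.getLogger(__name__)

__all__ = ["SweepSpec", "run_sweep", "DEFAULT_SIZES", "DEFAULT_PROPORTIONS"]

DEFAULT_SIZES = tuple(range(25, 501, 25))
DEFAULT_PROPORTIONS = (0.0, 0.1, 0.25, 0.5, 1.0)


@dataclasses.dataclass
class SweepSpec:
    """Grid of panel sizes and multi-In proportions to evaluate."""

    panel_sizes: Sequence[int] = DEFAULT_SIZES
    proportions_multi: Sequence[float] = DEFAULT_PROPORTIONS

    def __post_init__(self) -> None:
        sizes = list(self.panel_sizes)
        if any(s <= 0 for s in sizes):
            raise DataError("panel sizes must be positive")
        if any(b <= a for a, b in zip(sizes, sizes[1:])):
            raise DataError("panel sizes must be strictly increasing")
        if any(not 0.0 <= p <= 1.0 for p in self.proportions_multi):
            raise DataError("proportions must lie in [0, 1]")


def run_sweep(
    freqs: FreqTable,
    snp_map: SnpMap,
    genotypes: GenotypeMatrix,
    spec: SweepSpec,
    base_config: SelectionConfig | None = None,
    q_reference: AncestryMatrix | None = None,
    seed: int = 1,
) -> pd.DataFrame:
    """Evaluate every sweep cell; deterministic given inputs and seed.

    ``q_reference`` is the comparison standard; if omitted it is estimated
    from all available markers (the genome-wide baseline).  Returns a
    long-format frame with columns size, proportion, ancestry, correlation,
    rmse, status.
    """
    del seed  # selection and supervised estimation are deterministic
    if q_reference is None:
        f_all = SourceFreqs.from_freq_table(freqs)
        q_reference, _ = estimate_proportions(genotypes, f_all)
    rows: list[dict] = []
    for prop in spec.proportions_multi:
        for size in spec.panel_sizes:
            try:
                if base_config is None:
                    cfg = SelectionConfig(n_aims=size, proportion_multi=prop)
                else:
                    cfg = dataclasses.replace(
                        base_config, n_aims=size, proportion_multi=prop
                    )
                result = select_aims(freqs, snp_map, genotypes, cfg)
                f_panel = SourceFreqs.from_freq_table(
                    freqs.restrict(result.panel.snp_ids)
                )
                q_panel, _ = estimate_proportions(genotypes, f_panel)
                report = evaluate_panel(q_panel, q_reference)
                for _, rep in report.iterrows():
                    rows.append(
                        {
                            "size": size,
                            "proportion": prop,
                            "ancestry": rep["ancestry"],
                            "correlation": rep["correlation"],
                            "rmse": rep["rmse"],
                            "status": "ok",
                        }
                    )
            except Exception as exc:  # record the cell failure, keep sweeping
                logger.error("sweep cell (size=%d, prop=%.2f) failed: %s", size, prop, exc)
                rows.append(
                    {
                        "size": size,
                        "proportion": prop,
                        "ancestry": "",
                        "correlation": np.nan,
                        "rmse": np.nan,
                        "status": f"error: {exc}",
                    }
                )
    return pd.DataFrame(rows, columns=["size", "proportion", "ancestry", "correlation", "rmse", "status"])
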