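"""Group-versus-rest expression contrast (the low-fitness-family screen).

Averages each gene over one target group (e.g. a family with poor hatch
rate) and over all other samples within the same treatment stratum,
keeps genes where at least one average exceeds a floor, and screens the
target/other ratio against strict fold boundaries (> ratio_hi up,
< ratio_lo down). Control and LPS strata are never pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import ExpressionError, ExpressionMatrix
from . import network


@dataclass
class ContrastSpec:
    """One group-vs-rest screen within a treatment stratum.

    ``ratio_lo`` defaults to 0.67 as conventionally printed (not exactly
    1/1.5); both boundaries are strict.
    """

    target: str                  # value of group_col defining the target group
    stratum: str = "control"     # 'control' or 'LPS'
    group_col: str = "family"
    min_mean: float = 1.0
    ratio_hi: float = 1.5
    ratio_lo: float = 0.67
    pseudocount: float = 0.5     # used only when the denominator mean is 0

    def __post_init__(self) -> None:
        if not self.ratio_lo < 1.0 < self.ratio_hi:
            raise ValueError("require ratio_lo < 1 < ratio_hi")


@dataclass
class ContrastResult:
    table: pd.DataFrame          # mean_target, mean_other, ratio, eligible, direction
    up: list[str]
    down: list[str]
    n_target: int
    n_other: int


def group_contrast(matrix: ExpressionMatrix, spec: ContrastSpec) -> ContrastResult:
    """Per-gene target/other mean-ratio screen within one stratum.

    A gene is eligible iff max(mean_target, mean_other) > min_mean
    (strictly greater than 1 TPM by default); up iff ratio > ratio_hi,
    down iff ratio < ratio_lo, both strict.
    """
    stratum = matrix.stratum(spec.stratum)
    groups = stratum.samples[spec.group_col]
    in_target = (groups == spec.target).to_numpy()
    if not in_target.any() or in_target.all():
        raise ExpressionError(
            f"stratum {spec.stratum!r}: target group {spec.target!r} and its "
            "complement must both be nonempty"
        )
    mt = stratum.values.loc[:, in_target].mean(axis=1)
    mo = stratum.values.loc[:, ~in_target].mean(axis=1)
    eligible = np.maximum(mt, mo) > spec.min_mean
    denom = mo.where(mo > 0, spec.pseudocount)
    ratio = mt / denom
    direction = np.where(
        eligible & (ratio > spec.ratio_hi), "up",
        np.where(eligible & (ratio < spec.ratio_lo), "down", ""),
    )
    table = pd.DataFrame(
        {"mean_target": mt, "mean_other": mo, "ratio": ratio,
         "eligible": eligible, "direction": direction}
    )
    up = list(table.index[table["direction"] == "up"])
    down = list(table.index[table["direction"] == "down"])
    return ContrastResult(table, up, down, int(in_target.sum()), int((~in_target).sum()))


def contrast_enrichment(
    result: ContrastResult,
    gene_sets: dict[str, set[str]],
    universe: set[str] | list[str],
) -> dict[str, pd.DataFrame]:
    """Hypergeometric enrichment of the up and down lists (local
    replacement for the web annotation step)."""
    return {
        "up": network.gene_set_enrichment(result.up, gene_sets, universe),
        "down": network.gene_set_enrichment(result.down, gene_sets, universe),
    }
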