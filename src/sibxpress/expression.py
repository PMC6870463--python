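"""Per-gene expression screening statistics.

The screens implemented here target the signatures that sibling-mating
F2 designs expose in immune-cell transcriptomes:

* genes segregating a **null expression allele** show extreme
  between-bird variation (a near-zero homozygous class next to 1x and 2x
  functional-allele classes),
* **Z-linked** genes show a male/female expression ratio between 1
  (full dosage compensation) and 2 (no compensation),
* **LPS-inducible** genes show >2-fold paired induction in stimulated
  macrophages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class ExpressionError(ValueError):
    """Invalid expression matrix or screening request."""


def chromosome_class(chrom: str) -> str:
    """Map a contig name to {autosome, Z, W, unknown}."""
    c = str(chrom).lower().removeprefix("chr")
    if c == "z":
        return "Z"
    if c == "w":
        return "W"
    if c.isdigit():
        return "autosome"
    return "unknown"


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM matrix with sample and gene metadata.

    ``samples`` is indexed by sample id with columns ``individual``,
    ``sex`` ('M'/'F'), ``family``, ``generation``, ``treatment``
    ('control'/'LPS'); paired samples share an ``individual``.
    ``genes`` is indexed by gene id with at least a ``chromosome`` column.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ExpressionError("TPM values must be nonnegative")
        if list(self.values.columns) != list(self.samples.index):
            raise ExpressionError("sample metadata does not match matrix columns")
        if list(self.values.index) != list(self.genes.index):
            raise ExpressionError("gene metadata does not match matrix rows")
        for col in ("individual", "sex", "treatment"):
            if col not in self.samples.columns:
                raise ExpressionError(f"sample sheet lacks required column '{col}'")
        if "chromosome" not in self.genes.columns:
            raise ExpressionError("gene sheet lacks required column 'chromosome'")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def chrom_class(self) -> pd.Series:
        return self.genes["chromosome"].map(chromosome_class)

    def stratum(self, treatment: str) -> "ExpressionMatrix":
        """Sub-matrix of one treatment stratum ('control' or 'LPS')."""
        keep = self.samples.index[self.samples["treatment"] == treatment]
        if len(keep) == 0:
            raise ExpressionError(f"no samples in stratum {treatment!r}")
        return ExpressionMatrix(self.values[keep], self.samples.loc[keep], self.genes)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[gene_ids], self.samples, self.genes.loc[gene_ids]
        )

    # ---- TSV round trip --------------------------------------------------
    def to_tsv(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.values.rename_axis("gene").to_csv(f"{prefix}_expr.tsv", sep="\t")
        self.samples.rename_axis("sample").to_csv(f"{prefix}_samples.tsv", sep="\t")
        self.genes.rename_axis("gene").to_csv(f"{prefix}_genes.tsv", sep="\t")

    @classmethod
    def from_tsv(cls, expr: str, samples: str, genes: str) -> "ExpressionMatrix":
        values = pd.read_csv(expr, sep="\t", index_col=0)
        smeta = pd.read_csv(samples, sep="\t", index_col=0)
        gmeta = pd.read_csv(genes, sep="\t", index_col=0)
        return cls(values[list(smeta.index)], smeta, gmeta.loc[values.index])


# ---------------------------------------------------------------------------
# screens


def filter_expressed(matrix: ExpressionMatrix, min_max_tpm: float = 10.0) -> pd.Index:
    """Genes detectably expressed: retained iff max over samples >= threshold.

    Equivalently, transcripts whose maximum expression is below the
    detection threshold (default 10 TPM) are removed.
    """
    if matrix.values.empty:
        raise ExpressionError("empty expression matrix")
    return matrix.gene_ids[matrix.values.max(axis=1) >= min_max_tpm]


def max_min_ratio(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Per-gene max, min and the max/min fold-difference statistic.

    ``ratio`` is +inf when the minimum is zero (an expressed gene absent
    in at least one bird — the null-allele signature) and NaN for an
    all-zero gene; both raw extremes are always reported.
    """
    vmax = matrix.values.max(axis=1)
    vmin = matrix.values.min(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(vmin > 0, vmax / vmin, np.where(vmax > 0, np.inf, np.nan))
    return pd.DataFrame({"max": vmax, "min": vmin, "ratio": ratio}, index=matrix.gene_ids)


@dataclass
class VennSets:
    """Partition of extreme-variation genes across two treatment strata."""

    control_only: set[str]
    lps_only: set[str]
    shared: set[str]

    @property
    def union_size(self) -> int:
        return len(self.control_only) + len(self.lps_only) + len(self.shared)

    def counts(self) -> dict[str, int]:
        return {
            "control_only": len(self.control_only),
            "lps_only": len(self.lps_only),
            "shared": len(self.shared),
            "total": self.union_size,
        }

    def percentages(self) -> dict[str, float]:
        n = self.union_size
        if n == 0:
            return {"control_only": 0.0, "lps_only": 0.0, "shared": 0.0}
        return {
            "control_only": 100.0 * len(self.control_only) / n,
            "lps_only": 100.0 * len(self.lps_only) / n,
            "shared": 100.0 * len(self.shared) / n,
        }


def extreme_variation_flags(
    matrix: ExpressionMatrix, max_thresh: float = 20.0, min_thresh: float = 1.0
) -> pd.Series:
    """Extreme between-individual variation: max > 20 and min < 1 (strict)."""
    mm = max_min_ratio(matrix)
    return (mm["max"] > max_thresh) & (mm["min"] < min_thresh)


def extreme_variation_sets(
    control: ExpressionMatrix,
    lps: ExpressionMatrix,
    max_thresh: float = 20.0,
    min_thresh: float = 1.0,
) -> VennSets:
    """Venn partition of extreme-variation genes between strata."""
    cu, lu = set(control.gene_ids), set(lps.gene_ids)
    if cu != lu:
        diff = sorted((cu - lu) | (lu - cu))
        raise ExpressionError(f"gene universes differ between strata: {diff[:10]}...")
    cset = set(control.gene_ids[extreme_variation_flags(control, max_thresh, min_thresh)])
    lset = set(lps.gene_ids[extreme_variation_flags(lps, max_thresh, min_thresh)])
    return VennSets(cset - lset, lset - cset, cset & lset)


# ---------------------------------------------------------------------------
# allele-dosage grouping


@dataclass
class DosageGroups:
    """1-3 contiguous expression groups consistent with 0x/1x/2x allele dosage."""

    assignments: pd.Series        # sample -> group index, 0 = lowest-expressed
    group_means: list[float]      # TPM scale, ascending
    k: int
    additivity_score: float       # |m_mid - (m_low+m_high)/2| / m_high; NaN unless k == 3
    candidate_null: bool          # near-zero group well separated from the rest


def _partition_sse(logv: np.ndarray, bounds: tuple[int, ...]) -> float:
    sse = 0.0
    edges = (0, *bounds, len(logv))
    for a, b in zip(edges, edges[1:]):
        seg = logv[a:b]
        sse += float(((seg - seg.mean()) ** 2).sum())
    return sse


def classify_dosage_groups(
    values: pd.Series,
    max_groups: int = 3,
    penalty: float = 1.0,
    pseudocount: float = 0.5,
    null_max_tpm: float = 1.0,
    null_gap_fold: float = 5.0,
) -> DosageGroups:
    """Partition per-bird expression of one gene into 1-3 dosage classes.

    Samples are sorted and split into contiguous groups on the
    log2(TPM + pseudocount) axis; the number of groups k minimises the
    within-group sum of squares plus a BIC-style penalty per group
    (``penalty * k * log(n)`` added to ``n * log(SSE/n)``). Ties prefer
    fewer groups. The additivity score measures how well three group
    means fit an additive 0/1/2 functional-allele-copy model.

    The gene is a *candidate null* when the lowest group sits entirely
    below ``null_max_tpm`` TPM and is separated from the next group by at
    least ``max(null_gap_fold * group max, 2 * null_max_tpm)`` — a
    discrete near-zero class, not the tail of a continuous gradient.
    """
    values = pd.Series(values, dtype=float)
    n = len(values)
    if n < 4:
        raise ExpressionError(f"dosage grouping needs >= 4 samples, got {n}")
    order = np.argsort(values.to_numpy(), kind="stable")
    sorted_v = values.to_numpy()[order]
    logv = np.log2(sorted_v + pseudocount)

    best: tuple[float, int, tuple[int, ...]] | None = None
    from itertools import combinations

    for k in range(1, max_groups + 1):
        for bounds in combinations(range(1, n), k - 1):
            sse = _partition_sse(logv, bounds)
            score = n * np.log(sse / n + 1e-12) + penalty * k * np.log(n)
            if best is None or score < best[0] - 1e-12:
                best = (score, k, bounds)
    assert best is not None
    _, k, bounds = best

    edges = (0, *bounds, n)
    groups = np.empty(n, dtype=int)
    means = []
    for gi, (a, b) in enumerate(zip(edges, edges[1:])):
        groups[a:b] = gi
        means.append(float(sorted_v[a:b].mean()))
    assignments = pd.Series(index=values.index[order], data=groups).reindex(values.index)

    additivity = float("nan")
    if k == 3 and means[2] > 0:
        additivity = abs(means[1] - (means[0] + means[2]) / 2) / means[2]

    candidate_null = False
    if k >= 2:
        low_max = float(sorted_v[: edges[1]].max())
        next_min = float(sorted_v[edges[1]])
        gap_needed = max(null_gap_fold * low_max, 2.0 * null_max_tpm)
        candidate_null = low_max < null_max_tpm and next_min >= gap_needed
    return DosageGroups(assignments, means, k, additivity, candidate_null)


def null_candidate_screen(
    matrix: ExpressionMatrix,
    max_thresh: float = 20.0,
    min_thresh: float = 1.0,
    chrom_classes: tuple[str, ...] = ("autosome",),
    **dosage_kwargs,
) -> pd.DataFrame:
    """Null-expression-allele candidate screen over one treatment stratum.

    A gene is a candidate when it (a) meets the extreme-variation
    criterion (max > 20, min < 1) and (b) its dosage grouping isolates a
    well-separated near-zero class (see
    :func:`classify_dosage_groups`). Restricted to the given chromosome
    classes by default: W-restricted genes trivially show a near-zero
    male class and Z hemizygosity confounds the 0x/1x/2x logic, so sex
    chromosomes are reported by :func:`extreme_variation_flags` but not
    called here.

    Returns a frame indexed by screened gene with columns ``extreme``,
    ``k``, ``additivity``, ``candidate_null`` and ``near_zero_samples``
    (comma-joined sample ids of the near-zero group, '' if none).
    """
    keep = matrix.chrom_class().isin(chrom_classes)
    sub = matrix.subset_genes(matrix.gene_ids[keep.to_numpy()])
    flags = extreme_variation_flags(sub, max_thresh, min_thresh)
    rows = []
    for gene in sub.gene_ids:
        extreme = bool(flags.loc[gene])
        k, add, cand, low = 0, float("nan"), False, ""
        if extreme:
            dg = classify_dosage_groups(sub.values.loc[gene], **dosage_kwargs)
            k, add, cand = dg.k, dg.additivity_score, dg.candidate_null
            if cand:
                low = ",".join(sorted(dg.assignments.index[dg.assignments == 0]))
        rows.append({"extreme": extreme, "k": k, "additivity": add,
                     "candidate_null": cand, "near_zero_samples": low})
    return pd.DataFrame(rows, index=sub.gene_ids)


# ---------------------------------------------------------------------------
# sex-linked dosage


@dataclass
class SexRatioResult:
    table: pd.DataFrame        # per-gene mf_ratio + compensated flag
    median_ratio: float        # median male/female ratio over the gene class


def sex_ratio_analysis(
    matrix: ExpressionMatrix,
    chrom_class: str = "Z",
    min_max_tpm: float = 10.0,
    bootstrap_reps: int = 1000,
    seed: int = 0,
) -> SexRatioResult:
    """Male/female mean expression ratios for one chromosome class.

    Incomplete Z dosage compensation shows up as a median ratio between 1
    and 2. A gene is flagged ``compensated`` when a nonparametric
    bootstrap 95% interval of its ratio covers 1 (expression ratio not
    significantly different from 1).
    """
    sex = matrix.samples["sex"]
    male_ids = matrix.sample_ids[(sex == "M").to_numpy()]
    female_ids = matrix.sample_ids[(sex == "F").to_numpy()]
    if len(male_ids) < 2 or len(female_ids) < 2:
        raise ExpressionError("sex-ratio analysis needs >= 2 samples of each sex")

    keep = matrix.chrom_class() == chrom_class
    sub = matrix.values[keep.to_numpy()]
    sub = sub[sub.max(axis=1) >= min_max_tpm]
    male = sub[male_ids].to_numpy()
    female = sub[female_ids].to_numpy()
    # expressed in both sexes: the ratio is undefined otherwise
    both = (male.mean(axis=1) > 0) & (female.mean(axis=1) > 0)
    sub, male, female = sub[both], male[both], female[both]
    ratio = male.mean(axis=1) / female.mean(axis=1)

    rng = np.random.default_rng(seed)
    mi = rng.integers(0, male.shape[1], size=(bootstrap_reps, male.shape[1]))
    fi = rng.integers(0, female.shape[1], size=(bootstrap_reps, female.shape[1]))
    bm = male[:, mi].mean(axis=2)      # genes x reps
    bf = female[:, fi].mean(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        bratio = bm / bf
    lo = np.nanpercentile(bratio, 2.5, axis=1)
    hi = np.nanpercentile(bratio, 97.5, axis=1)
    table = pd.DataFrame(
        {"mf_ratio": ratio, "ci_lo": lo, "ci_hi": hi,
         "compensated": (lo <= 1.0) & (1.0 <= hi)},
        index=sub.index,
    )
    median = float(np.median(ratio)) if len(ratio) else float("nan")
    return SexRatioResult(table, median)


# ---------------------------------------------------------------------------
# LPS response


@dataclass
class LpsResponse:
    table: pd.DataFrame    # per-gene mean_control, mean_lps, fold, induced, repressed
    n_induced: int
    n_repressed: int
    n_pairs: int


def lps_response(
    matrix: ExpressionMatrix,
    min_max_tpm: float = 10.0,
    fold: float = 2.0,
    pseudocount: float = 0.5,
) -> LpsResponse:
    """Paired LPS fold changes with >2-fold induced/repressed counts.

    Only individuals with both a control and an LPS sample contribute;
    unpaired samples are excluded with a warning. Fold change is
    (mean LPS + pc) / (mean control + pc) over expressed genes; induced
    iff fold > threshold (strict), repressed iff fold < 1/threshold.
    """
    s = matrix.samples
    ctrl = s[s["treatment"] == "control"]
    lps = s[s["treatment"] == "LPS"]
    paired = sorted(set(ctrl["individual"]) & set(lps["individual"]))
    unpaired = (set(ctrl["individual"]) ^ set(lps["individual"]))
    if unpaired:
        warnings.warn(f"excluding {len(unpaired)} unpaired individual(s)", stacklevel=2)
    if not paired:
        raise ExpressionError("no control/LPS pairs found")
    ctrl_ids = [ctrl.index[ctrl["individual"] == i][0] for i in paired]
    lps_ids = [lps.index[lps["individual"] == i][0] for i in paired]

    vals = matrix.values[ctrl_ids + lps_ids]
    expressed = vals.max(axis=1) >= min_max_tpm
    mc = matrix.values[ctrl_ids].mean(axis=1)[expressed]
    ml = matrix.values[lps_ids].mean(axis=1)[expressed]
    fc = (ml + pseudocount) / (mc + pseudocount)
    table = pd.DataFrame(
        {"mean_control": mc, "mean_lps": ml, "fold": fc,
         "induced": fc > fold, "repressed": fc < 1.0 / fold}
    )
    return LpsResponse(table, int(table["induced"].sum()),
                       int(table["repressed"].sum()), len(paired))
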