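"""Variant panel filtration, consequence bookkeeping and breed contrasts.

Quality thresholds pass at >= (the criteria state minima without
strictness); a variant is dropped when its post-masking missing-call
rate strictly exceeds the maximum. Missing genotypes are excluded from
allele-frequency denominators; they are mean-imputed only inside the
PCA. Hemizygous Z/W calls contribute one allele to frequencies and are
tallied separately from the diploid hom/het classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import FilterCriteria
from .panel import ABSENT, MISSING, GenotypePanel


@dataclass
class FilterResult:
    panel: GenotypePanel
    n_in: int
    n_out: int
    n_low_site_quality: int
    n_calls_masked: int
    n_high_missing: int


def filter_panel(panel: GenotypePanel, criteria: FilterCriteria) -> FilterResult:
    """Apply site-quality, genotype-quality and missingness filtration.

    1. drop variants with site quality below ``min_site_quality``;
    2. mask genotype calls with quality below ``min_genotype_quality``;
    3. drop variants whose post-masking missing rate exceeds
       ``max_missing_rate`` (rate over samples where the locus exists).
    """
    if panel.n_variants == 0:
        warnings.warn("filtering an empty panel", stacklevel=2)
        return FilterResult(panel, 0, 0, 0, 0, 0)

    qual_ok = panel.variants["qual"].to_numpy() >= criteria.min_site_quality
    n_low_q = int((~qual_ok).sum())
    kept = panel.subset_variants(qual_ok)

    geno = kept.genotypes.copy()
    n_masked = 0
    if kept.genotype_quality is not None:
        low = kept.genotype_quality < criteria.min_genotype_quality
        n_masked = int(low.sum())
        mask3 = low[:, :, None] & (geno != ABSENT)
        geno[mask3] = MISSING

    exists = ~(geno == ABSENT).all(axis=2)
    miss = (geno == MISSING).any(axis=2) & exists
    with np.errstate(invalid="ignore"):
        rate = miss.sum(axis=1) / np.maximum(exists.sum(axis=1), 1)
    rate_ok = rate <= criteria.max_missing_rate
    n_high_missing = int((~rate_ok).sum())

    out = GenotypePanel(
        kept.variants[rate_ok].reset_index(drop=True),
        kept.samples,
        geno[rate_ok],
        kept.genotype_quality[rate_ok] if kept.genotype_quality is not None else None,
    )
    return FilterResult(out, panel.n_variants, out.n_variants,
                        n_low_q, n_masked, n_high_missing)


# ---------------------------------------------------------------------------
# consequence taxonomy

HIGH_IMPACT = frozenset(
    {"stop_gained", "stop_lost", "start_lost", "splice_acceptor", "splice_donor",
     "frameshift"}
)

_CATEGORY_PATTERNS = [
    ("stop_gained", ("stop_gained", "stop gain", "stopgain")),
    ("stop_lost", ("stop_lost", "stop loss", "loss of stop", "stop los")),
    ("start_lost", ("start_lost", "start los", "loss of start")),
    ("splice_acceptor", ("splice_acceptor",)),
    ("splice_donor", ("splice_donor",)),
    ("frameshift", ("frameshift",)),
    ("missense_deleterious", ("missense_deleterious", "deleterious")),
]

_KNOWN_BENIGN = ("missense", "synonymous", "intron", "intergenic", "utr", "upstream",
                 "downstream", "other", "non_coding", "splice_region", "indel")


def classify_consequence(annotation: str) -> str:
    """Map a raw consequence string to the working taxonomy.

    Categories: the five complete loss-of-function classes, frameshift,
    missense_deleterious, and 'other'. Unknown non-empty annotations map
    to 'other' with a warning.
    """
    raw = (annotation or "").strip().lower().replace(" ", "_")
    token = raw.split("&")[0]
    probe = f"{token} {raw}"
    for category, needles in _CATEGORY_PATTERNS:
        if any(n.replace(" ", "_") in probe for n in needles):
            return category
    if raw and not any(b in probe for b in _KNOWN_BENIGN):
        warnings.warn(f"unknown consequence annotation {annotation!r}", stacklevel=2)
    return "other"


def classify_consequences(panel: GenotypePanel) -> pd.DataFrame:
    """Per-variant category and HIGH-impact flag, plus per-category tallies.

    HIGH covers stop gained/lost, start lost, splice acceptor/donor and
    frameshift; frameshifts are also tallied separately so either
    counting convention is recoverable.
    """
    cats = panel.variants["consequence"].map(classify_consequence)
    high = cats.isin(HIGH_IMPACT)
    return pd.DataFrame({"category": cats.to_numpy(), "high_impact": high.to_numpy()},
                        index=panel.variants.index)


def consequence_tally(classified: pd.DataFrame) -> pd.Series:
    tally = classified["category"].value_counts()
    tally.loc["HIGH_total"] = int(classified["high_impact"].sum())
    tally.loc["HIGH_snv_only"] = int(
        (classified["high_impact"] & (classified["category"] != "frameshift")).sum()
    )
    return tally


# ---------------------------------------------------------------------------
# genotype classes


def genotype_class_counts(panel: GenotypePanel) -> pd.DataFrame:
    """Per-variant (hom_alt, het, hom_ref, missing, hemi, absent) counts.

    The six classes partition the sample set at every variant. A call is
    missing when any existing allele slot is uncalled; hemizygous calls
    (one existing slot) form their own class.
    """
    g = panel.genotypes
    exists = g != ABSENT
    n_exist = exists.sum(axis=2)
    any_missing = ((g == MISSING) & exists).any(axis=2)
    alt = ((g == 1) & exists).sum(axis=2)

    absent = n_exist == 0
    missing = any_missing & ~absent
    diploid = (n_exist == 2) & ~missing
    hemi = (n_exist == 1) & ~missing
    counts = pd.DataFrame(
        {
            "hom_alt": (diploid & (alt == 2)).sum(axis=1),
            "het": (diploid & (alt == 1)).sum(axis=1),
            "hom_ref": (diploid & (alt == 0)).sum(axis=1),
            "missing": missing.sum(axis=1),
            "hemi": hemi.sum(axis=1),
            "absent": absent.sum(axis=1),
        },
        index=panel.variants.index,
    )
    assert (counts.sum(axis=1) == panel.n_samples).all()
    return counts


def table_summary(panel: GenotypePanel) -> pd.DataFrame:
    """Variant summary table: gene, locus, quality, consequence and
    genotype-class counts (one row per variant)."""
    counts = genotype_class_counts(panel)
    cls = classify_consequences(panel)
    return pd.concat(
        [panel.variants[["gene", "chrom", "pos", "ref", "alt", "qual", "consequence"]],
         cls, counts],
        axis=1,
    )


# ---------------------------------------------------------------------------
# breed contrasts


def breed_frequency_contrast(
    panel: GenotypePanel,
    breeds: pd.Series | None = None,
    near_fixed_hi: float = 0.95,
    near_fixed_lo: float = 0.05,
) -> pd.DataFrame:
    """Per-variant alt-allele frequencies in two breeds and fixation flags.

    Frequencies are computed from non-missing calls only (hemizygous
    calls contribute one allele). ``near_fixed_opposite`` is true when
    one breed's frequency is >= ``near_fixed_hi`` and the other's is
    <= ``near_fixed_lo``. Sites where a breed has no usable calls get
    NaN frequencies and ``defined`` False.
    """
    if breeds is None:
        breeds = panel.samples["breed"]
    labels = sorted({b for b in breeds if b})
    if len(labels) != 2:
        raise ValueError(f"need exactly two breed labels, got {labels}")

    g = panel.genotypes
    called = g >= 0
    out: dict[str, np.ndarray] = {}
    for li, label in enumerate(labels):
        cols = (breeds == label).to_numpy()
        n_alleles = called[:, cols, :].sum(axis=(1, 2))
        n_alt = (g[:, cols, :] == 1).sum(axis=(1, 2))
        with np.errstate(invalid="ignore", divide="ignore"):
            out[f"af_{li + 1}"] = np.where(n_alleles > 0, n_alt / np.maximum(n_alleles, 1), np.nan)
    af1, af2 = out["af_1"], out["af_2"]
    defined = ~np.isnan(af1) & ~np.isnan(af2)
    if (~defined).any():
        warnings.warn(
            f"{int((~defined).sum())} site(s) with all-missing calls in one breed",
            stacklevel=2,
        )
    near = defined & (
        ((af1 >= near_fixed_hi) & (af2 <= near_fixed_lo))
        | ((af2 >= near_fixed_hi) & (af1 <= near_fixed_lo))
    )
    return pd.DataFrame(
        {"breed_1": labels[0], "breed_2": labels[1], "af_1": af1, "af_2": af2,
         "delta": np.abs(af1 - af2), "near_fixed_opposite": near, "defined": defined},
        index=panel.variants.index,
    )


# ---------------------------------------------------------------------------
# genotype PCA


def genotype_pca(panel: GenotypePanel, n_components: int = 10) -> pd.DataFrame:
    """Sample coordinates on the top principal components of the
    0/1/2 alt-dosage matrix (missing calls mean-imputed per variant).

    Returns a samples x components frame; the explained variance ratio
    is attached as ``frame.attrs['explained_variance_ratio']``.
    """
    from sklearn.decomposition import PCA

    if panel.n_samples < 3 or panel.n_variants < 2:
        raise ValueError("PCA needs >= 3 samples and >= 2 variants")
    dose = panel.alt_dosage().T  # samples x variants
    col_mean = np.nanmean(dose, axis=0)
    col_mean = np.nan_to_num(col_mean)  # all-missing variants impute to 0
    nan = np.isnan(dose)
    dose[nan] = np.broadcast_to(col_mean, dose.shape)[nan]

    k = min(n_components, panel.n_samples - 1, panel.n_variants)
    if k < n_components:
        warnings.warn(f"reducing components from {n_components} to {k}", stacklevel=2)
    pca = PCA(n_components=k, svd_solver="full", random_state=0)
    coords = pca.fit_transform(dose)
    frame = pd.DataFrame(coords, index=panel.samples.index,
                         columns=[f"PC{i + 1}" for i in range(k)])
    frame.attrs["explained_variance_ratio"] = pca.explained_variance_ratio_
    return frame
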