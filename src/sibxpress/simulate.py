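"""Synthetic breeding-design and expression simulator.

Generates the full study design with known ground truth: two divergent
founder breeds (with breed-near-fixed alternative alleles and rare
heterozygous null expression alleles), F0 crosses, F1 brother-sister
pairs, gene-dropped F2 genotypes, and TPM expression matrices following
an additive cis model with partial Z dosage compensation, W-restricted
genes, a trans-regulated LPS-inducible module, per-sample mesenchymal
contamination, and multiplicative log-normal noise.

All randomness derives from the single ``SimulationConfig.seed``, split
into one named substream per stage, so identical configs reproduce
identical outputs byte for byte and stages are independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ConfigError, SimulationConfig
from .expression import ExpressionMatrix
from .panel import ABSENT, MISSING, GenotypePanel, PanelError, Pedigree, VARIANT_COLUMNS

# fixed substream indices per stage — reordering would silently change outputs
_STREAMS = {"founders": 0, "pedigree": 1, "gene_drop": 2, "expression": 3}

MODULES = ("constitutive", "mesenchyme", "lps_trans_target", "lps_induced", "lps_repressed")

_HIGH_CSQ = ["stop_gained", "stop_lost", "start_lost", "splice_acceptor_variant",
             "splice_donor_variant"]
# relative prevalence of loss-of-function classes among high-impact SNVs
_HIGH_W = np.array([628.0, 142.0, 282.0, 20.0, 26.0])
_HIGH_W /= _HIGH_W.sum()

TRANS_LOCUS_GENE = "TRANSREG1"


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stage],)))


@dataclass
class GroundTruth:
    """Everything the analysis is supposed to recover.

    ``genes`` is indexed by gene id with columns: chromosome, module,
    ref_effect / alt_effect (TPM contribution per allele copy; a null
    allele has effect exactly 0), lps_log2fc, null_founder (id of the
    single founder heterozygous for the null allele, '' otherwise).
    """

    genes: pd.DataFrame
    trans_locus: tuple[str, int]
    mesenchyme_fraction: pd.Series | None = None  # filled by simulate_expression

    def __post_init__(self) -> None:
        if not self.genes["module"].isin(MODULES).all():
            raise ConfigError("every gene must belong to exactly one module class")
        null = self.genes["null_founder"] != ""
        if not (self.genes.loc[null, "alt_effect"] == 0).all():
            raise ConfigError("null-allele genes must have alt effect exactly 0")

    @property
    def null_genes(self) -> pd.Index:
        return self.genes.index[self.genes["null_founder"] != ""]


# ---------------------------------------------------------------------------
# founders


def simulate_founders(config: SimulationConfig) -> tuple[GenotypePanel, GroundTruth]:
    """Two breed-labelled founder sets genotyped at one cis locus per gene.

    ``breed_fixed_fraction`` of autosomal loci get alternative-allele
    frequencies >= 0.95 in one breed and <= 0.05 in the other;
    ``het_null_fraction`` of autosomal genes (outside the mesenchyme
    module) carry a zero-effect alternative allele heterozygous in
    exactly one founder. Z/W loci respect sex: males ZZ with no W,
    females one Z and one W.
    """
    if config.n_founders_per_breed <= 0:
        raise ConfigError("zero founders requested")
    rng = _rng(config.seed, "founders")

    # -- gene / locus layout
    n_a, n_z, n_w = config.n_autosomal_genes, config.n_z_genes, config.n_w_genes
    gene_ids = (
        [f"GA{i + 1:04d}" for i in range(n_a)]
        + [f"GZ{i + 1:04d}" for i in range(n_z)]
        + [f"GW{i + 1:04d}" for i in range(n_w)]
    )
    chroms = (
        [f"chr{(i % 10) + 1}" for i in range(n_a)] + ["chrZ"] * n_z + ["chrW"] * n_w
    )
    positions: list[int] = []
    counters: dict[str, int] = {}
    for c in chroms:
        counters[c] = counters.get(c, 0) + 1
        positions.append(counters[c] * 10_000 + 1)

    # -- module assignment (autosomal genes only)
    planted = (
        config.mesenchyme_module_size + config.trans_module_size
        + config.n_lps_induced + config.n_lps_repressed
    )
    if planted > n_a:
        raise ConfigError("planted module sizes exceed the autosomal gene count")
    auto_perm = rng.permutation(n_a)
    module = np.array(["constitutive"] * len(gene_ids), dtype=object)
    cursor = 0
    for name, size in (
        ("mesenchyme", config.mesenchyme_module_size),
        ("lps_trans_target", config.trans_module_size),
        ("lps_induced", config.n_lps_induced),
        ("lps_repressed", config.n_lps_repressed),
    ):
        module[auto_perm[cursor:cursor + size]] = name
        cursor += size

    # -- cis effects
    lo, hi = config.baseline_tpm_range
    baseline = 2 ** rng.uniform(np.log2(lo), np.log2(hi), size=len(gene_ids))
    ref_effect = baseline / 2.0
    alt_effect = ref_effect.copy()

    # -- locus categories on autosomes: null, breed-fixed, background
    null_eligible = [
        i for i in range(n_a) if module[i] != "mesenchyme"
    ]
    n_null = int(round(config.het_null_fraction * n_a))
    n_null = min(n_null, len(null_eligible))
    null_idx = rng.choice(null_eligible, size=n_null, replace=False) if n_null else np.array([], int)
    remaining = np.setdiff1d(np.arange(n_a), null_idx)
    n_fixed = int(round(config.breed_fixed_fraction * n_a))
    n_fixed = min(n_fixed, len(remaining))
    fixed_idx = rng.choice(remaining, size=n_fixed, replace=False) if n_fixed else np.array([], int)

    is_null = np.zeros(len(gene_ids), bool)
    is_null[null_idx] = True
    is_fixed = np.zeros(len(gene_ids), bool)
    is_fixed[fixed_idx] = True
    # loci-length views (gene loci + the trailing trans-regulator locus)
    is_null_locus = np.append(is_null, False)
    is_fixed_locus = np.append(is_fixed, False)

    # autosomal non-null loci may carry a cis-regulatory (nonzero) alt effect
    cis_var = (np.arange(len(gene_ids)) < n_a) & ~is_null
    alt_effect[cis_var] = ref_effect[cis_var] * 2 ** rng.uniform(-1, 1, int(cis_var.sum()))
    alt_effect[is_null] = 0.0

    # -- LPS fold changes
    lps_lfc = np.zeros(len(gene_ids))
    for name, (loc, scale) in (
        ("lps_induced", config.lps_up_log2fc),
        ("lps_repressed", config.lps_down_log2fc),
    ):
        m = module == name
        lps_lfc[m] = rng.normal(loc, scale, int(m.sum()))
    m = module == "lps_trans_target"
    lps_lfc[m] = np.abs(rng.normal(*config.lps_up_log2fc, int(m.sum())))

    # -- founder individuals (alternating sex within breed)
    def founder_ids(prefix: str) -> list[str]:
        return [f"{prefix}{i + 1:02d}" for i in range(config.n_founders_per_breed)]

    broilers, layers = founder_ids("BR"), founder_ids("LY")
    ids = broilers + layers
    sexes = ["M" if i % 2 == 0 else "F" for i in range(config.n_founders_per_breed)] * 2
    breeds = ["broiler"] * len(broilers) + ["layer"] * len(layers)
    samples = pd.DataFrame(
        {"breed": breeds, "sex": sexes, "generation": 0, "family": ""},
        index=pd.Index(ids, name="id"),
    )

    # -- per-breed allele frequencies, plus the trans-regulator locus
    n_loci = len(gene_ids) + 1  # + trans locus
    af = np.empty((n_loci, 2))  # columns: broiler, layer
    common = rng.uniform(0.1, 0.9, n_loci)
    af[:, 0] = common
    af[:, 1] = common
    hi_f = rng.uniform(0.95, 1.0, n_loci)
    lo_f = rng.uniform(0.0, 0.05, n_loci)
    flip = rng.random(n_loci) < 0.5
    for i in np.flatnonzero(is_fixed_locus):
        af[i] = (hi_f[i], lo_f[i]) if flip[i] else (lo_f[i], hi_f[i])
    af[is_null_locus] = 0.0  # null alleles enter via a single het founder below
    trans_row = n_loci - 1
    af[trans_row] = (hi_f[trans_row], lo_f[trans_row])  # broiler-fixed trans allele

    # -- draw founder genotypes
    geno = np.zeros((n_loci, len(ids), 2), dtype=np.int8)
    breed_col = np.array([0 if b == "broiler" else 1 for b in breeds])
    p = af[:, breed_col]  # loci x samples
    geno[:, :, 0] = rng.random((n_loci, len(ids))) < p
    geno[:, :, 1] = rng.random((n_loci, len(ids))) < p

    # near-fixed loci: cap the minority-allele count at floor(0.05 * n_alleles)
    # so realized breed frequencies honour the (>=0.95, <=0.05) definition even
    # in small founder panels ("almost fixed" is a property of the panel itself)
    fixed_loci = np.append(np.flatnonzero(is_fixed_locus), trans_row)
    for bi in (0, 1):
        cols = np.flatnonzero(breed_col == bi)
        n_alleles = 2 * len(cols)
        cap = int(0.05 * n_alleles)
        for i in fixed_loci:
            major = np.int8(1) if af[i, bi] >= 0.5 else np.int8(0)
            p_minor = 1 - af[i, bi] if major == 1 else af[i, bi]
            k = min(int(rng.binomial(n_alleles, p_minor)), cap)
            geno[i, cols, :] = major
            if k:
                slots = rng.choice(n_alleles, size=k, replace=False)
                geno[i, cols[slots // 2], slots % 2] = 1 - major

    is_z = np.array([c == "chrZ" for c in chroms] + [False])
    is_w = np.array([c == "chrW" for c in chroms] + [False])
    female = np.array([s == "F" for s in sexes])
    zf = geno[np.ix_(is_z, female)]
    zf[:, :, 1] = ABSENT  # females carry a single Z in slot 0
    geno[np.ix_(is_z, female)] = zf
    geno[np.ix_(is_w, ~female)] = ABSENT  # no W in males
    wf = geno[np.ix_(is_w, female)]
    wf[:, :, 1] = ABSENT  # single W in slot 0
    geno[np.ix_(is_w, female)] = wf

    # -- plant the null alleles: exactly one founder heterozygous
    null_founders = np.array([""] * len(gene_ids), dtype=object)
    for i in null_idx:
        carrier = int(rng.integers(0, len(ids)))
        null_founders[i] = ids[carrier]
        geno[i, :, :] = 0
        geno[i, carrier] = (0, 1)

    # -- variant annotations
    consequences = np.array(
        rng.choice(["other", "missense_deleterious", "synonymous_variant"],
                   size=n_loci, p=[0.8, 0.1, 0.1]),
        dtype=object,
    )
    consequences[is_null_locus] = rng.choice(_HIGH_CSQ, size=int(is_null.sum()), p=_HIGH_W)
    consequences[trans_row] = "other"
    qlo, qhi = config.site_quality_range
    quals = rng.uniform(qlo, qhi, n_loci)
    glo, ghi = config.genotype_quality_range
    gq = rng.uniform(glo, ghi, (n_loci, len(ids))).astype(np.float32)

    trans_chrom, trans_pos = "chr1", 90_000_001
    variants = pd.DataFrame(
        {
            "chrom": chroms + [trans_chrom],
            "pos": positions + [trans_pos],
            "ref": "C",
            "alt": "T",
            "qual": quals,
            "gene": gene_ids + [TRANS_LOCUS_GENE],
            "consequence": consequences,
        },
        columns=VARIANT_COLUMNS,
    )
    panel = GenotypePanel(variants, samples, geno, gq)

    genes = pd.DataFrame(
        {
            "chromosome": chroms,
            "module": module,
            "ref_effect": ref_effect,
            "alt_effect": alt_effect,
            "lps_log2fc": lps_lfc,
            "null_founder": null_founders,
        },
        index=pd.Index(gene_ids, name="gene"),
    )
    truth = GroundTruth(genes, (trans_chrom, trans_pos))
    return panel, truth


# ---------------------------------------------------------------------------
# pedigree


def build_pedigree(config: SimulationConfig) -> Pedigree:
    """F0 broiler x layer pairs -> F1 full-sib pairs -> F2 families.

    Each F1 mating is one brother-sister pair (one male, one female from
    the same F0 cross); F2 families are labelled FAM_A, FAM_B, ... and
    F2 sexes are assigned randomly 1:1.
    """
    rng = _rng(config.seed, "pedigree")
    n = config.n_founders_per_breed
    broilers = [(f"BR{i + 1:02d}", "M" if i % 2 == 0 else "F") for i in range(n)]
    layers = [(f"LY{i + 1:02d}", "M" if i % 2 == 0 else "F") for i in range(n)]

    rows: list[dict] = [
        {"id": i, "sire": "", "dam": "", "sex": s, "generation": 0, "family": "",
         "breed": "broiler"}
        for i, s in broilers
    ] + [
        {"id": i, "sire": "", "dam": "", "sex": s, "generation": 0, "family": "",
         "breed": "layer"}
        for i, s in layers
    ]

    # F0 crosses: pair each broiler with an opposite-sex layer (swap within
    # consecutive sex-alternating pairs)
    f0_pairs: list[tuple[str, str]] = []  # (sire, dam)
    for i, (bid, bsex) in enumerate(broilers):
        j = i + 1 if i % 2 == 0 else i - 1
        if j >= len(layers):
            continue
        lid, lsex = layers[j]
        if bsex == lsex:
            continue
        f0_pairs.append((bid, lid) if bsex == "M" else (lid, bid))
    if not f0_pairs:
        raise ConfigError("need at least one founder of each sex per breed")

    def fam_label(j: int) -> str:
        return f"FAM_{chr(ord('A') + j)}" if j < 26 else f"FAM_{j + 1}"

    for j in range(config.n_f1_pairs):
        sire0, dam0 = f0_pairs[j % len(f0_pairs)]
        brother, sister = f"F1_{j + 1:02d}M", f"F1_{j + 1:02d}F"
        for fid, fsex in ((brother, "M"), (sister, "F")):
            rows.append({"id": fid, "sire": sire0, "dam": dam0, "sex": fsex,
                         "generation": 1, "family": "", "breed": ""})
        fam = fam_label(j)
        for k in range(config.n_f2_per_family):
            sex = "M" if rng.random() < 0.5 else "F"
            rows.append({"id": f"F2_{fam[4:]}{k + 1:02d}", "sire": brother,
                         "dam": sister, "sex": sex, "generation": 2, "family": fam,
                         "breed": ""})
    return Pedigree(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# gene drop


def gene_drop(pedigree: Pedigree, founders: GenotypePanel, seed: int) -> GenotypePanel:
    """Drop founder alleles through the pedigree under Mendelian rules.

    Autosomes: one allele per parent, uniform among the parent's two.
    Z: sons receive one Z from each parent (uniform among the sire's
    two); daughters receive one of the sire's Z alleles and the dam's W
    at W loci. Calls carry no missingness; hemizygous loci use slot 0
    with slot 1 absent.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS["gene_drop"],)))
    ped = pedigree.table.sort_values(["generation"], kind="stable").reset_index(drop=True)
    founder_rows = ped[ped["generation"] == 0]
    unknown = set(founder_rows["id"]) - set(founders.sample_ids)
    if unknown:
        raise PanelError(f"pedigree founders not genotyped: {sorted(unknown)}")

    ids = list(ped["id"])
    idx_of = {i: k for k, i in enumerate(ids)}
    n_var = founders.n_variants
    G = np.full((n_var, len(ids), 2), ABSENT, dtype=np.int8)
    src_of = {sid: k for k, sid in enumerate(founders.sample_ids)}
    fsrc = [src_of[i] for i in founder_rows["id"]]
    fdst = [idx_of[i] for i in founder_rows["id"]]
    G[:, fdst, :] = founders.genotypes[:, fsrc, :]
    if (G[:, fdst, :] == MISSING).any():
        raise PanelError("all founders must be genotyped at all loci")

    chrom = founders.variants["chrom"].to_numpy()
    is_z = chrom == "chrZ"
    is_w = chrom == "chrW"
    is_auto = ~(is_z | is_w)

    def pick(parent_geno: np.ndarray, bits: np.ndarray) -> np.ndarray:
        # parent_geno: (n_var, n_ind, 2); bits: (n_var, n_ind)
        return np.take_along_axis(parent_geno, bits[..., None], axis=2)[..., 0]

    for g in sorted(set(ped["generation"])):
        if g == 0:
            continue
        block = ped[ped["generation"] == g]
        ci = np.array([idx_of[i] for i in block["id"]])
        si = np.array([idx_of[i] for i in block["sire"]])
        di = np.array([idx_of[i] for i in block["dam"]])
        male = (block["sex"] == "M").to_numpy()

        sire_g = G[:, si, :]
        dam_g = G[:, di, :]
        bits = rng.integers(0, 2, size=(n_var, len(ci)))
        from_sire = pick(sire_g, bits)
        bits2 = rng.integers(0, 2, size=(n_var, len(ci)))
        from_dam = pick(dam_g, bits2)

        child = np.full((n_var, len(ci), 2), ABSENT, dtype=np.int8)
        # autosomes: paternal slot 0, maternal slot 1
        child[is_auto, :, 0] = from_sire[is_auto]
        child[is_auto, :, 1] = from_dam[is_auto]
        # Z: everyone gets one of the sire's two Z alleles in slot 0
        zslice = child[is_z]
        zslice[:, :, 0] = from_sire[is_z]
        # sons also get the dam's single Z (her slot 0)
        zslice[:, male, 1] = dam_g[is_z][:, male, 0]
        child[is_z] = zslice
        # W: daughters get the dam's W (her slot 0)
        wslice = child[is_w]
        wslice[:, ~male, 0] = dam_g[is_w][:, ~male, 0]
        child[is_w] = wslice
        G[:, ci, :] = child

    samples = ped.set_index("id")[["breed", "sex", "generation", "family"]]
    gq = np.full((n_var, len(ids)), 99.0, dtype=np.float32)
    # founders keep their original call qualities
    if founders.genotype_quality is not None:
        gq[:, fdst] = founders.genotype_quality[:, fsrc]
    return GenotypePanel(founders.variants.copy(), samples, G, gq)


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    genotypes: GenotypePanel,
    truth: GroundTruth,
    design: pd.DataFrame,
    config: SimulationConfig,
) -> ExpressionMatrix:
    """TPM expression for the samples in ``design`` under the cis model.

    Expected expression of gene g in sample s =
    (sum of cis allele effects) x Z-dosage term x LPS term x mesenchyme
    term, realised with multiplicative 2**N(0, noise_sd_log2) noise.
    W genes emit exactly 0 in males; hom-null birds emit exactly 0.

    ``design`` needs columns: individual, sex, treatment ('control' or
    'LPS'), indexed by sample id. The drawn per-sample mesenchyme
    fractions are recorded on ``truth.mesenchyme_fraction``.
    """
    rng = _rng(config.seed, "expression")
    for col in ("individual", "sex", "treatment"):
        if col not in design.columns:
            raise ConfigError(f"design sheet lacks column '{col}'")
    bad = set(design["treatment"]) - {"control", "LPS"}
    if bad:
        raise ConfigError(f"unknown treatment label(s): {sorted(bad)}")
    unknown = set(design["individual"]) - set(genotypes.sample_ids)
    if unknown:
        raise ConfigError(f"design refers to ungenotyped individual(s): {sorted(unknown)}")
    has_sex_genes = (truth.genes["chromosome"].isin(["chrZ", "chrW"])).any()
    if has_sex_genes and not set(design["sex"]) <= {"M", "F"}:
        raise ConfigError("samples need M/F sex labels when Z/W genes are simulated")

    genes = truth.genes
    gene_to_row = {g: i for i, g in enumerate(genotypes.variants["gene"])}
    rows = np.array([gene_to_row[g] for g in genes.index])
    ind_idx = np.array([genotypes.sample_ids.index(i) for i in design["individual"]])
    G = genotypes.genotypes[np.ix_(rows, ind_idx)]  # genes x samples x 2

    ref_e = genes["ref_effect"].to_numpy()[:, None]
    alt_e = genes["alt_effect"].to_numpy()[:, None]
    expected = ref_e * (G == 0).sum(axis=2) + alt_e * (G == 1).sum(axis=2)

    female = (design["sex"] == "F").to_numpy()
    z_rows = (genes["chromosome"] == "chrZ").to_numpy()
    expected[np.ix_(z_rows, female)] *= config.dosage_compensation_factor

    # LPS term
    lps_cols = (design["treatment"] == "LPS").to_numpy()
    lfc = np.zeros_like(expected)
    resp = genes["module"].isin(["lps_induced", "lps_repressed"]).to_numpy()
    lfc[np.ix_(resp, lps_cols)] = genes["lps_log2fc"].to_numpy()[resp][:, None]
    tgt = (genes["module"] == "lps_trans_target").to_numpy()
    if tgt.any():
        trow = genotypes.locus_index(*truth.trans_locus)
        talleles = genotypes.genotypes[trow, ind_idx]
        n_alt = (talleles == 1).sum(axis=1).astype(float)
        scale = config.trans_effect_per_alt_allele ** n_alt
        lfc[np.ix_(tgt, lps_cols)] = (
            genes["lps_log2fc"].to_numpy()[tgt][:, None] * scale[None, lps_cols]
        )
    expected = expected * 2.0 ** lfc

    # mesenchymal contamination
    flo, fhi = config.mesenchyme_fraction_range
    frac = rng.uniform(flo, fhi, size=len(design))
    mes = (genes["module"] == "mesenchyme").to_numpy()
    expected[mes] *= frac[None, :]
    if config.renormalize_tpm:
        expected[~mes] *= (1.0 - frac)[None, :]

    noise = 2.0 ** rng.normal(0.0, config.noise_sd_log2, size=expected.shape) \
        if config.noise_sd_log2 > 0 else 1.0
    values = expected * noise

    w_rows = (genes["chromosome"] == "chrW").to_numpy()
    values[np.ix_(w_rows, ~female)] = 0.0

    truth.mesenchyme_fraction = pd.Series(frac, index=design.index, name="mesenchyme_fraction")
    vdf = pd.DataFrame(values, index=genes.index, columns=design.index)
    smeta = design.copy()
    if "family" not in smeta.columns:
        smeta["family"] = ""
    if "generation" not in smeta.columns:
        smeta["generation"] = 2
    gmeta = genes[["chromosome", "module"]].copy()
    return ExpressionMatrix(vdf, smeta, gmeta)


# ---------------------------------------------------------------------------
# one-call cohort


@dataclass
class SimulatedCohort:
    """Full simulated study: genotypes, pedigree, truth, paired expression."""

    config: SimulationConfig
    founders: GenotypePanel
    pedigree: Pedigree
    panel: GenotypePanel          # founders + F1 + F2
    truth: GroundTruth
    design: pd.DataFrame
    expression: ExpressionMatrix  # paired control/LPS samples of all F2 birds


def f2_design(pedigree: Pedigree) -> pd.DataFrame:
    """Paired control/LPS sample sheet covering every F2 bird."""
    f2 = pedigree.generation(2)
    rows = []
    for r in f2.itertuples():
        for suffix, treat in (("C", "control"), ("L", "LPS")):
            rows.append({"sample": f"{r.id}_{suffix}", "individual": r.id,
                         "sex": r.sex, "family": r.family, "generation": 2,
                         "treatment": treat})
    return pd.DataFrame(rows).set_index("sample")


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Simulate the complete design from founders to paired expression."""
    founders, truth = simulate_founders(config)
    pedigree = build_pedigree(config)
    panel = gene_drop(pedigree, founders, config.seed)
    design = f2_design(pedigree)
    expr = simulate_expression(panel, truth, design, config)
    return SimulatedCohort(config, founders, pedigree, panel, truth, design, expr)
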