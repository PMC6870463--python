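"""Mendelian expectations for the F0 -> F1 sibling -> F2 design.

Two headline facts of the design, both recovered here analytically and
by gene-drop simulation: a variant heterozygous in one grandparent is
homozygous in ~1/16 of F2 birds, and a variant for which the two
grandparents are homozygous for opposite alleles (all F1 matings
het x het) is homozygous in 25% of F2 progeny.

"Random mating" within F1 is interpreted as one brother-sister pair
drawn without genotype selection; selecting F1 pairs by genotype (the
breeding strategy) is a separate operation.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import product
from typing import Literal

import numpy as np
import pandas as pd

from .panel import GenotypePanel, PanelError, Pedigree, VARIANT_COLUMNS

Genotype = Literal["hom_ref", "het", "hom_alt"]
GENOTYPES: tuple[Genotype, ...] = ("hom_ref", "het", "hom_alt")

_P_ALT = {"hom_ref": Fraction(0), "het": Fraction(1, 2), "hom_alt": Fraction(1)}


@dataclass
class CrossSpec:
    """A single-locus cross: two F0 founder genotypes and the design shape."""

    founder_genotypes: tuple[Genotype, Genotype]
    chromosome: Literal["autosome", "Z"] = "autosome"
    n_f1_pairs: int = 1
    n_f2_per_family: int = 1

    def __post_init__(self) -> None:
        if len(self.founder_genotypes) != 2:
            raise ValueError("exactly two F0 parents per cross")
        for g in self.founder_genotypes:
            if g not in GENOTYPES:
                raise ValueError(f"unknown genotype {g!r}")


def offspring_distribution(g_sire: Genotype, g_dam: Genotype) -> dict[Genotype, Fraction]:
    """Exact offspring genotype law for one autosomal mating (Punnett)."""
    p, q = _P_ALT[g_sire], _P_ALT[g_dam]
    return {
        "hom_alt": p * q,
        "het": p * (1 - q) + (1 - p) * q,
        "hom_ref": (1 - p) * (1 - q),
    }


def expected_f2_genotype_probs(spec: CrossSpec) -> dict[Genotype, Fraction]:
    """Exact rational genotype law of a random F2 bird at an autosomal locus.

    Enumerates the F1 genotype pair (a random brother-sister pair; sib
    genotypes are conditionally independent given the F0 parents) and
    averages the resulting F2 offspring laws. The triple sums to 1
    exactly.
    """
    if spec.chromosome != "autosome":
        raise ValueError("use expected_f2_z_probs for Z-linked loci")
    f1 = offspring_distribution(*spec.founder_genotypes)
    out = {g: Fraction(0) for g in GENOTYPES}
    for (g1, p1), (g2, p2) in product(f1.items(), f1.items()):
        for g, p in offspring_distribution(g1, g2).items():
            out[g] += p1 * p2 * p
    assert sum(out.values()) == 1
    return out


def expected_f2_z_probs(
    sire_genotype: Genotype, dam_allele: Literal["ref", "alt"]
) -> dict[str, dict[str, Fraction]]:
    """Sex-stratified F2 law for a Z-linked locus.

    The F0 sire is ZZ (a diploid genotype); the F0 dam carries a single
    Z. Returns the diploid triple for F2 males and the hemizygous
    ref/alt law for F2 females.
    """
    p_sire = _P_ALT[sire_genotype]
    p_dam = Fraction(1) if dam_allele == "alt" else Fraction(0)

    # F1 son: one Z from each parent -> diploid law
    f1_son = {
        "hom_alt": p_sire * p_dam,
        "het": p_sire * (1 - p_dam) + (1 - p_sire) * p_dam,
        "hom_ref": (1 - p_sire) * (1 - p_dam),
    }
    # F1 daughter: single Z from the sire
    f1_dau = {"alt": p_sire, "ref": 1 - p_sire}

    male = {g: Fraction(0) for g in GENOTYPES}
    female = {"ref": Fraction(0), "alt": Fraction(0)}
    for (gs, ps), (ad, pd_) in product(f1_son.items(), f1_dau.items()):
        w = ps * pd_
        p_from_son = _P_ALT[gs]
        p_from_dau = Fraction(1) if ad == "alt" else Fraction(0)
        male["hom_alt"] += w * p_from_son * p_from_dau
        male["het"] += w * (p_from_son * (1 - p_from_dau) + (1 - p_from_son) * p_from_dau)
        male["hom_ref"] += w * (1 - p_from_son) * (1 - p_from_dau)
        female["alt"] += w * p_from_son
        female["ref"] += w * (1 - p_from_son)
    assert sum(male.values()) == 1 and sum(female.values()) == 1
    return {"male": male, "female": female}


# ---------------------------------------------------------------------------
# stochastic twin


@dataclass
class SegregationEstimate:
    frequencies: dict[Genotype, float]
    standard_errors: dict[Genotype, float]
    expected: dict[Genotype, Fraction]
    n_replicates: int

    def within(self, n_se: float = 3.0) -> bool:
        """All empirical frequencies within n_se binomial SEs of expectation."""
        return all(
            abs(self.frequencies[g] - float(self.expected[g]))
            <= n_se * max(self.standard_errors[g], 1e-12)
            for g in GENOTYPES
        )


def _genotype_to_alleles(g: Genotype) -> tuple[int, int]:
    return {"hom_ref": (0, 0), "het": (0, 1), "hom_alt": (1, 1)}[g]


def simulate_f2_genotype_freqs(
    spec: CrossSpec, n_replicates: int, seed: int
) -> SegregationEstimate:
    """Monte-Carlo twin of :func:`expected_f2_genotype_probs`.

    Builds ``n_replicates`` independent four-member families (F0 pair,
    one F1 sib pair, one F2 bird) and runs the gene-drop transmission
    engine at a single autosomal locus.
    """
    from .simulate import gene_drop

    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    r = np.arange(n_replicates).astype(str)
    tag = {p: np.char.add(p, r) for p in "SDBGX"}
    empty = np.full(n_replicates, "")

    def block(ids, sire, dam, sex, gen, fam, breed):
        return pd.DataFrame(
            {"id": ids, "sire": sire, "dam": dam, "sex": sex, "generation": gen,
             "family": fam, "breed": breed}
        )

    ped = Pedigree(pd.concat(
        [
            block(tag["S"], empty, empty, "M", 0, "", "a"),
            block(tag["D"], empty, empty, "F", 0, "", "b"),
            block(tag["B"], tag["S"], tag["D"], "M", 1, "", ""),
            block(tag["G"], tag["S"], tag["D"], "F", 1, "", ""),
            block(tag["X"], tag["B"], tag["G"], "M", 2, r, ""),
        ],
        ignore_index=True,
    ))

    founder_ids = [i for r in range(n_replicates) for i in (f"S{r}", f"D{r}")]
    g1, g2 = spec.founder_genotypes
    geno = np.zeros((1, len(founder_ids), 2), dtype=np.int8)
    geno[0, 0::2] = _genotype_to_alleles(g1)
    geno[0, 1::2] = _genotype_to_alleles(g2)
    variants = pd.DataFrame(
        [{"chrom": "chr1", "pos": 1, "ref": "C", "alt": "T", "qual": 999.0,
          "gene": "FOCAL", "consequence": ""}],
        columns=VARIANT_COLUMNS,
    )
    samples = pd.DataFrame(
        {"breed": ["a", "b"] * n_replicates, "sex": ["M", "F"] * n_replicates,
         "generation": 0, "family": ""},
        index=pd.Index(founder_ids, name="id"),
    )
    founders = GenotypePanel(variants, samples, geno)
    dropped = gene_drop(ped, founders, seed)

    pos = {sid: k for k, sid in enumerate(dropped.sample_ids)}
    idx = [pos[f"X{k}"] for k in range(n_replicates)]
    alt = (dropped.genotypes[0, idx] == 1).sum(axis=1)
    freqs = {
        "hom_ref": float((alt == 0).mean()),
        "het": float((alt == 1).mean()),
        "hom_alt": float((alt == 2).mean()),
    }
    expected = expected_f2_genotype_probs(spec)
    ses = {
        g: float(np.sqrt(float(expected[g]) * (1 - float(expected[g])) / n_replicates))
        for g in GENOTYPES
    }
    return SegregationEstimate(freqs, ses, expected, n_replicates)


# ---------------------------------------------------------------------------
# F1 pair selection


def select_f1_pairs(
    panel: GenotypePanel, pedigree: Pedigree, loci: list[tuple[str, int]]
) -> list[tuple[str, str]]:
    """Brother-sister F1 pairs heterozygous at every listed locus.

    This is the breeding-selection step: F1 birds are selected by
    genotype so that alleles of interest segregate 1:2:1 in their F2
    family. Returns (brother, sister) id pairs; may be empty.
    """
    rows = [panel.locus_index(c, p) for c, p in loci]  # raises naming the locus
    f1 = pedigree.generation(1)
    het_ids = set(panel.sample_ids)
    for vi in rows:
        g = panel.genotypes[vi]
        het = {
            sid for si, sid in enumerate(panel.sample_ids)
            if set(g[si][g[si] >= 0].tolist()) == {0, 1}
        }
        het_ids &= het

    pairs = []
    by_parents: dict[tuple[str, str], list] = {}
    for r in f1.itertuples():
        by_parents.setdefault((r.sire, r.dam), []).append(r)
    for sibs in by_parents.values():
        males = [r.id for r in sibs if r.sex == "M" and r.id in het_ids]
        females = [r.id for r in sibs if r.sex == "F" and r.id in het_ids]
        pairs += [(m, f) for m in males for f in females]
    return sorted(pairs)
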