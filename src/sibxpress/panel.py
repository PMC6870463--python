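"""Genotype panel and pedigree containers with VCF / TSV input-output.

Genotype encoding (``int8`` allele slots, two per sample per variant):

* ``0`` — reference allele
* ``1`` — alternative allele
* ``MISSING`` (−1) — no call
* ``ABSENT`` (−2) — the slot does not exist for that individual
  (second Z slot in females, both W slots in males, second slot of any
  hemizygous call)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = np.int8(-1)
ABSENT = np.int8(-2)

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "qual", "gene", "consequence"]


class PanelError(ValueError):
    """Structural problem with a genotype panel or pedigree."""


@dataclass
class Pedigree:
    """Individuals with sire/dam/sex/generation, supporting gene drop.

    ``table`` columns: id, sire, dam, sex ('M'/'F'), generation (0-based),
    family ('' for founders/F1), breed ('' for crossbreds). Founders have
    sire == dam == ''.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"id", "sire", "dam", "sex", "generation", "family", "breed"}
        missing = required - set(self.table.columns)
        if missing:
            raise PanelError(f"pedigree table lacks columns: {sorted(missing)}")
        ids = set(self.table["id"])
        if len(ids) != len(self.table):
            raise PanelError("duplicate individual ids in pedigree")
        for col in ("sire", "dam"):
            parents = set(self.table[col]) - {""}
            unknown = parents - ids
            if unknown:
                raise PanelError(f"pedigree refers to unknown {col}(s): {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> list[str]:
        return list(self.table["id"])

    def generation(self, g: int) -> pd.DataFrame:
        return self.table[self.table["generation"] == g]

    def is_acyclic(self) -> bool:
        """True when no individual is its own ancestor."""
        parents = {
            row.id: {p for p in (row.sire, row.dam) if p}
            for row in self.table.itertuples()
        }
        state: dict[str, int] = {}

        def visit(node: str) -> bool:
            if state.get(node) == 1:
                return False
            if state.get(node) == 2:
                return True
            state[node] = 1
            ok = all(visit(p) for p in parents.get(node, ()))
            state[node] = 2
            return ok

        return all(visit(i) for i in parents)


@dataclass
class GenotypePanel:
    """A variant-by-sample genotype matrix with site and call metadata."""

    variants: pd.DataFrame
    samples: pd.DataFrame  # indexed by sample id; columns breed/sex/generation/family
    genotypes: np.ndarray  # (n_variants, n_samples, 2) int8
    genotype_quality: np.ndarray | None = None  # (n_variants, n_samples) float32

    def __post_init__(self) -> None:
        missing = set(VARIANT_COLUMNS) - set(self.variants.columns)
        if missing:
            raise PanelError(f"variant table lacks columns: {sorted(missing)}")
        if self.genotypes.shape != (len(self.variants), len(self.samples), 2):
            raise PanelError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{len(self.variants)} variants x {len(self.samples)} samples"
            )
        if (self.variants["pos"] < 1).any():
            raise PanelError("variant positions must be 1-based (>= 1)")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    # ---- subsetting -----------------------------------------------------
    def subset_variants(self, mask: np.ndarray) -> "GenotypePanel":
        mask = np.asarray(mask)
        gq = self.genotype_quality[mask] if self.genotype_quality is not None else None
        return GenotypePanel(
            self.variants[mask].reset_index(drop=True),
            self.samples,
            self.genotypes[mask],
            gq,
        )

    def subset_samples(self, ids: Sequence[str]) -> "GenotypePanel":
        idx = [self.sample_ids.index(i) for i in ids]
        gq = self.genotype_quality[:, idx] if self.genotype_quality is not None else None
        return GenotypePanel(
            self.variants.copy(), self.samples.loc[list(ids)], self.genotypes[:, idx], gq
        )

    # ---- derived quantities ---------------------------------------------
    def alt_dosage(self) -> np.ndarray:
        """Alt-allele dosage per variant x sample; NaN when no usable call."""
        g = self.genotypes
        called = g >= 0
        dose = np.where(called, g, 0).sum(axis=2).astype(float)
        any_missing = (g == MISSING).any(axis=2)
        n_called = called.sum(axis=2)
        dose[any_missing | (n_called == 0)] = np.nan
        return dose

    def locus_index(self, chrom: str, pos: int) -> int:
        hit = np.flatnonzero(
            (self.variants["chrom"] == chrom).to_numpy()
            & (self.variants["pos"] == pos).to_numpy()
        )
        if len(hit) == 0:
            raise PanelError(f"locus {chrom}:{pos} not present in panel")
        return int(hit[0])

    # ---- VCF output ------------------------------------------------------
    def to_vcf(self, path: str | Path) -> None:
        """Write the panel as an uncompressed VCF 4.2 text file."""
        contigs = list(dict.fromkeys(self.variants["chrom"]))
        lines = ["##fileformat=VCFv4.2", "##source=sibxpress"]
        lines += [f"##contig=<ID={c}>" for c in contigs]
        lines.append('##INFO=<ID=CSQ,Number=1,Type=String,Description="Consequence">')
        lines.append('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id">')
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        lines.append('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">')
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
        header += self.sample_ids
        lines.append("\t".join(header))

        gq = self.genotype_quality
        for vi, row in enumerate(self.variants.itertuples()):
            info_parts = []
            if row.gene:
                info_parts.append(f"GENE={row.gene}")
            if row.consequence:
                info_parts.append(f"CSQ={row.consequence}")
            info = ";".join(info_parts) or "."
            fields = [
                row.chrom, str(int(row.pos)), ".", row.ref, row.alt,
                f"{row.qual:g}", "PASS", info, "GT:GQ",
            ]
            for si in range(self.n_samples):
                a1, a2 = self.genotypes[vi, si]
                gt = _encode_gt(a1, a2)
                q = int(gq[vi, si]) if gq is not None else 99
                fields.append(f"{gt}:{q}")
            lines.append("\t".join(fields))
        Path(path).write_text("\n".join(lines) + "\n")


def _encode_gt(a1: int, a2: int) -> str:
    def one(a: int) -> str:
        return "." if a == MISSING else str(int(a))

    if a1 == ABSENT and a2 == ABSENT:
        return "."
    if a2 == ABSENT:
        return one(a1)
    return f"{one(a1)}/{one(a2)}"


_CSQ_VOCAB = {
    "stop_gained", "stop_lost", "start_lost", "splice_acceptor_variant",
    "splice_donor_variant", "splice_acceptor", "splice_donor", "frameshift",
    "frameshift_variant", "missense_deleterious", "missense_variant",
    "synonymous_variant", "intron_variant", "intergenic_variant", "other",
}


def _consequence_from_info(variant, keys: Iterable[str]) -> str:
    """Pull a consequence token from INFO (first transcript, first effect)."""
    for key in keys:
        raw = variant.INFO.get(key)
        if raw is None:
            continue
        token = str(raw).split(",")[0]
        if "|" in token:
            for f in token.split("|"):
                f = f.strip().lower()
                if f in _CSQ_VOCAB or f.endswith("_variant"):
                    return f.split("&")[0]
            return ""
        return token.split("&")[0].strip()
    return ""


def read_vcf(
    path: str | Path,
    samples_meta: pd.DataFrame | None = None,
    consequence_keys: Sequence[str] = ("CSQ", "ANN"),
) -> GenotypePanel:
    """Load a VCF 4.x file (gzip ok) into a :class:`GenotypePanel`.

    Multi-allelic records are split into biallelic ones; calls involving a
    different alternative allele than the split record's are set missing.
    Haploid calls occupy one allele slot with the second marked absent.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    var_rows: list[dict] = []
    geno_rows: list[np.ndarray] = []
    gq_rows: list[np.ndarray] = []
    for v in vcf:
        try:
            raw_gq = v.format("GQ")
        except KeyError:
            raw_gq = None
        gq = np.asarray(
            raw_gq.reshape(-1) if raw_gq is not None else np.full(len(sample_ids), 99),
            dtype=np.float32,
        )
        csq = _consequence_from_info(v, consequence_keys)
        gene = v.INFO.get("GENE") or ""
        calls = v.genotypes  # [a1, a2, phased] or [a, phased]
        for alt_idx, alt in enumerate(v.ALT, start=1):
            g = np.full((len(sample_ids), 2), MISSING, dtype=np.int8)
            for si, call in enumerate(calls):
                alleles = call[:-1]
                if len(alleles) == 1 and alleles[0] < 0:
                    # haploid '.' encodes a locus the sample does not carry
                    g[si] = (ABSENT, ABSENT)
                    continue
                slots = []
                for a in alleles:
                    if a < 0:
                        slots.append(MISSING)
                    elif a == 0:
                        slots.append(np.int8(0))
                    elif a == alt_idx:
                        slots.append(np.int8(1))
                    else:
                        slots.append(MISSING)  # other alt in a split record
                while len(slots) < 2:
                    slots.append(ABSENT)
                g[si] = slots[:2]
            var_rows.append(
                {
                    "chrom": v.CHROM, "pos": v.POS, "ref": v.REF, "alt": alt,
                    "qual": float(v.QUAL) if v.QUAL is not None else 0.0,
                    "gene": gene, "consequence": csq,
                }
            )
            geno_rows.append(g)
            gq_rows.append(gq)
    variants = pd.DataFrame(var_rows, columns=VARIANT_COLUMNS)
    genotypes = (
        np.stack(geno_rows) if geno_rows else np.empty((0, len(sample_ids), 2), np.int8)
    )
    gqa = np.stack(gq_rows) if gq_rows else np.empty((0, len(sample_ids)), np.float32)
    if samples_meta is None:
        samples_meta = pd.DataFrame(
            {"breed": "", "sex": "", "generation": -1, "family": ""},
            index=pd.Index(sample_ids, name="id"),
        )
    else:
        samples_meta = samples_meta.loc[sample_ids]
    return GenotypePanel(variants, samples_meta, genotypes, gqa)
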