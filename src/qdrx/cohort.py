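"""Case-control cohort container and plain-text / VCF serialization.

A :class:`Cohort` bundles three aligned pieces:

* ``samples`` — one row per sample: id, phenotype (1 = case, 0 = control),
  optional matched ``pair_id``, optional ``population`` label;
* ``dosages`` — samples x variants allele-dosage matrix with entries
  {0, 1, 2} or NaN for missing;
* ``variants`` — one row per variant: id, chrom, pos, mapped gene, GWAS
  log odds ratio ``beta`` and association p-value ``p``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

SAMPLE_COLUMNS = ["sample_id", "phenotype", "pair_id", "population"]
VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "gene", "beta", "p"]

CASE = 1
CONTROL = 0


@dataclass
class Cohort:
    samples: pd.DataFrame
    dosages: np.ndarray
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.variants = self.variants.reset_index(drop=True)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")
        if not set(self.samples["phenotype"]).issubset({CASE, CONTROL}):
            raise ValueError("phenotype must be 0 (control) or 1 (case)")
        if self.variants["variant_id"].duplicated().any():
            raise ValueError("variant ids must be unique")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("sample ids must be unique")
        self.check_pair_integrity()

    # ------------------------------------------------------------------
    def check_pair_integrity(self) -> None:
        """Every non-null pair_id must cover exactly one case and one control."""
        if "pair_id" not in self.samples or self.samples["pair_id"].isna().all():
            return
        paired = self.samples.dropna(subset=["pair_id"])
        grp = paired.groupby("pair_id")["phenotype"]
        sizes = grp.size()
        cases = grp.sum()
        if not ((sizes == 2) & (cases == 1)).all():
            bad = sizes.index[(sizes != 2) | (cases != 1)].tolist()
            raise ValueError(f"pairs without exactly one case and one control: {bad[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def phenotype(self) -> np.ndarray:
        return self.samples["phenotype"].to_numpy(dtype=int)

    def variant_index(self, variant_ids) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.variants["variant_id"])}
        missing = [v for v in variant_ids if v not in lookup]
        if missing:
            raise KeyError(f"variants not in cohort: {missing[:5]}")
        return np.array([lookup[v] for v in variant_ids], dtype=int)

    def subset_variants(self, variant_ids) -> "Cohort":
        idx = self.variant_index(variant_ids)
        return Cohort(
            samples=self.samples.copy(),
            dosages=self.dosages[:, idx].copy(),
            variants=self.variants.iloc[idx].reset_index(drop=True),
        )

    def subset_samples(self, mask: np.ndarray) -> "Cohort":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(int)
        return Cohort(
            samples=self.samples.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[idx].copy(),
            variants=self.variants.copy(),
        )

    # -- plain-text serialization --------------------------------------
    def write_tsv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.samples[SAMPLE_COLUMNS].to_csv(out / "samples.tsv", sep="\t", index=False)
        self.variants[VARIANT_COLUMNS].to_csv(out / "gwas.tsv", sep="\t", index=False)
        dmat = pd.DataFrame(
            self.dosages,
            index=self.samples["sample_id"],
            columns=self.variants["variant_id"],
        )
        dmat.to_csv(out / "dosages.tsv", sep="\t")

    @classmethod
    def read_tsv(cls, in_dir: str | Path) -> "Cohort":
        inp = Path(in_dir)
        samples = pd.read_csv(inp / "samples.tsv", sep="\t")
        variants = pd.read_csv(inp / "gwas.tsv", sep="\t")
        dmat = pd.read_csv(inp / "dosages.tsv", sep="\t", index_col=0)
        dmat = dmat.loc[samples["sample_id"], variants["variant_id"].astype(str)]
        return cls(samples=samples, dosages=dmat.to_numpy(float), variants=variants)

    # -- VCF --------------------------------------------------------------
    def write_vcf(self, path: str | Path) -> None:
        """Write genotypes as an uncompressed VCFv4.2 with GT fields only."""
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            chroms = self.variants["chrom"].astype(str).unique()
            for c in chroms:
                fh.write(f"##contig=<ID={c}>\n")
            header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
            header += list(self.samples["sample_id"].astype(str))
            fh.write("\t".join(header) + "\n")
            for j, row in self.variants.iterrows():
                gts = [
                    gt_map.get(self.dosages[i, j], "./.")
                    for i in range(self.n_samples)
                ]
                fields = [
                    str(row["chrom"]), str(int(row["pos"])), str(row["variant_id"]),
                    "A", "G", ".", "PASS", ".", "GT",
                ] + gts
                fh.write("\t".join(fields) + "\n")

    @classmethod
    def read_vcf(cls, vcf_path: str | Path, samples_tsv: str | Path,
                 gwas_tsv: str | Path) -> "Cohort":
        """Load genotypes from a VCF (GT field) plus phenotype/GWAS sidecars."""
        from cyvcf2 import VCF

        samples = pd.read_csv(samples_tsv, sep="\t")
        gwas = pd.read_csv(gwas_tsv, sep="\t")
        vcf = VCF(str(vcf_path), gts012=True)
        order = {s: i for i, s in enumerate(vcf.samples)}
        rows, ids = [], []
        for rec in vcf:
            g = rec.gt_types.astype(float)  # 0/1/2, 3 = unknown
            g[g == 3] = np.nan
            rows.append(g)
            ids.append(rec.ID)
        dos = np.vstack(rows).T  # samples x variants in VCF sample order
        idx = [order[s] for s in samples["sample_id"].astype(str)]
        dos = dos[idx]
        gwas = gwas.set_index("variant_id").loc[ids].reset_index()
        return cls(samples=samples, dosages=dos, variants=gwas)
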