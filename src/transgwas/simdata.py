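"""Synthetic multi-ancestry GWAS data.

Genotype panels are drawn under a Balding-Nichols model: each ancestry's
population allele frequency is Beta-distributed around a shared ancestral
frequency with divergence parameter F (Fst).  Within-block linkage
disequilibrium is induced by a Gaussian copula over latent haplotype
variables, thresholded at the population frequency, so LD is tunable and
fully seeded.  Phenotypes are additive-polygenic with controllable
heritability plus an environmental shift along a latent geographic axis --
the residual-stratification confounder the downstream diagnostics target.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class AncestrySpec:
    """One ancestry group in a simulated panel.

    Parameters
    ----------
    label : name of the group.
    fst : Balding-Nichols divergence from the ancestral population, in [0, 1).
    n_samples : number of diploid samples (>= 2).
    strat_axis_value : position on the latent geographic/ancestry axis along
        which any environmental confounding acts.
    """

    label: str
    fst: float
    n_samples: int
    strat_axis_value: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fst < 1.0):
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")


@dataclass(frozen=True)
class TraitArchitecture:
    """Additive polygenic trait architecture.

    ``h2`` is the narrow-sense heritability of the genetic component;
    ``strat_delta`` is a purely environmental phenotype shift per unit of the
    stratification axis (it is *not* counted in h2).
    """

    n_causal: int
    h2: float
    effect_dist: Callable[[np.random.Generator, int], np.ndarray] | None = None
    strat_delta: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError(f"h2 must be in [0, 1], got {self.h2}")
        if self.h2 > 0 and self.n_causal == 0:
            raise ValueError("h2 > 0 with n_causal == 0 is inconsistent")


@dataclass
class GenotypePanel:
    """A samples x variants dosage panel with variant metadata.

    ``variants`` is a DataFrame with columns SNP, CHR, POS, REF, ALT (1-based
    positions, VCF convention); ``dosages`` holds values in [0, 2] with one
    row per sample; ``sample_ancestry`` gives each sample's ancestry label.
    """

    variants: pd.DataFrame
    dosages: np.ndarray
    sample_ids: list[str]
    sample_ancestry: list[str]
    ancestries: dict[str, AncestrySpec]
    info: np.ndarray | None = None
    pop_freqs: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if len(self.variants) != m:
            raise ValueError("variant table does not match dosage matrix")
        if len(self.sample_ids) != n or len(self.sample_ancestry) != n:
            raise ValueError("sample metadata does not match dosage matrix")
        if self.variants["SNP"].duplicated().any():
            raise ValueError("variant ids must be unique")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")
        for _, sub in self.variants.groupby("CHR", sort=False):
            pos = sub["POS"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError("positions must be strictly increasing per chromosome")
        if self.info is None:
            self.info = np.ones(m)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    @property
    def axis_values(self) -> np.ndarray:
        return np.array(
            [self.ancestries[a].strat_axis_value for a in self.sample_ancestry]
        )

    def alt_freqs(self) -> np.ndarray:
        return self.dosages.mean(axis=0) / 2.0

    def subset_samples(self, index: Sequence[int], relabel: bool = False) -> "GenotypePanel":
        index = np.asarray(index, dtype=int)
        return GenotypePanel(
            variants=self.variants.copy(),
            dosages=self.dosages[index],
            sample_ids=[self.sample_ids[i] for i in index],
            sample_ancestry=[self.sample_ancestry[i] for i in index],
            ancestries=dict(self.ancestries),
            info=None if self.info is None else self.info.copy(),
        )


def _default_maf_dist(rng: np.random.Generator, size: int) -> np.ndarray:
    return rng.uniform(0.05, 0.95, size=size)


def _block_layout(n_variants: int, ld_block_spec: Sequence[tuple[int, float]]):
    """Expand (size, r) block specs, cycled, to cover n_variants."""
    blocks = []
    i, j = 0, 0
    spec = list(ld_block_spec) if ld_block_spec else [(1, 0.0)]
    while i < n_variants:
        size, r = spec[j % len(spec)]
        size = min(size, n_variants - i)
        blocks.append((i, size, float(r)))
        i += size
        j += 1
    return blocks


def draw_panel(
    ancestries: Sequence[AncestrySpec],
    n_variants: int,
    ld_block_spec: Sequence[tuple[int, float]] | None = None,
    ancestral_maf_dist: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int = 0,
    chromosome: str = "1",
    spacing_bp: int = 5000,
    fractional: bool = False,
    info_dist: Callable[[np.random.Generator, int], np.ndarray] | None = None,
) -> GenotypePanel:
    """Draw a multi-ancestry genotype panel under Balding-Nichols divergence.

    Per-ancestry population frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F)
    around the ancestral frequency p (F=0 degenerates to p itself).  Within
    each LD block, haplotype alleles come from thresholding equicorrelated
    Gaussian latents (correlation r), giving tunable positive LD.  With
    ``fractional`` the hard genotypes are perturbed into [0, 2] dosages
    (rounded to 6 decimals) to exercise imputation-dosage code paths.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = np.random.default_rng(seed)
    ancestries = list(ancestries)
    if ancestral_maf_dist is None:
        ancestral_maf_dist = _default_maf_dist
    p_anc = np.clip(ancestral_maf_dist(rng, n_variants), 1e-6, 1 - 1e-6)

    pop_freqs = {}
    for spec in ancestries:
        if spec.fst == 0.0:
            pop_freqs[spec.label] = p_anc.copy()
        else:
            f = spec.fst
            a = p_anc * (1 - f) / f
            b = (1 - p_anc) * (1 - f) / f
            pop_freqs[spec.label] = np.clip(rng.beta(a, b), 1e-6, 1 - 1e-6)

    blocks = _block_layout(n_variants, ld_block_spec or [(1, 0.0)])
    total_n = sum(s.n_samples for s in ancestries)
    dosages = np.empty((total_n, n_variants), dtype=np.float32)
    sample_ids, sample_anc = [], []
    row = 0
    for spec in ancestries:
        n = spec.n_samples
        freqs = pop_freqs[spec.label]
        # latent < Phi^-1(p) -> carry the ALT allele
        thresh = stats.norm.ppf(freqs).astype(np.float32)
        geno = np.zeros((n, n_variants), dtype=np.uint8)
        for _hap in range(2):
            for start, size, r in blocks:
                eps = rng.standard_normal((n, size), dtype=np.float32)
                if r > 0:
                    shared = rng.standard_normal((n, 1), dtype=np.float32)
                    eps = np.float32(np.sqrt(r)) * shared + np.float32(np.sqrt(1 - r)) * eps
                geno[:, start : start + size] += eps < thresh[start : start + size]
        dosages[row : row + n] = geno
        sample_ids.extend(f"{spec.label}_{i:05d}" for i in range(n))
        sample_anc.extend([spec.label] * n)
        row += n

    if fractional:
        dosages = np.clip(
            dosages.astype(np.float64) + rng.normal(0.0, 0.05, dosages.shape), 0.0, 2.0
        )
        dosages = np.round(dosages, 6)

    variants = pd.DataFrame(
        {
            "SNP": [f"rs{i + 1}" for i in range(n_variants)],
            "CHR": chromosome,
            "POS": np.arange(1, n_variants + 1) * spacing_bp,
            "REF": "A",
            "ALT": "G",
        }
    )
    info = info_dist(rng, n_variants) if info_dist is not None else np.ones(n_variants)
    return GenotypePanel(
        variants=variants,
        dosages=dosages,
        sample_ids=sample_ids,
        sample_ancestry=sample_anc,
        ancestries={s.label: s for s in ancestries},
        info=np.asarray(info, dtype=float),
        pop_freqs=pd.DataFrame(pop_freqs),
    )


@dataclass
class PhenotypeTruth:
    """Ground truth for a simulated phenotype: causal ids and scaled effects."""

    causal_ids: list[str]
    effects: np.ndarray
    genetic_values: np.ndarray


def simulate_phenotypes(
    panel: GenotypePanel,
    arch: TraitArchitecture,
    seed: int = 0,
) -> tuple[pd.DataFrame, PhenotypeTruth]:
    """Simulate an additive polygenic phenotype over a panel.

    phenotype = genetic value (variance h2) + strat_delta * axis + noise,
    with noise scaled so the genetic + noise variance is 1; the environmental
    axis term sits on top, exactly as a residual-stratification confounder
    would.  Age and sex covariates are drawn independently of genotype.
    """
    if panel.n_variants == 0 or panel.n_samples == 0:
        raise ValueError("panel must be nonempty")
    if arch.n_causal > panel.n_variants:
        raise ValueError("n_causal exceeds panel variant count")
    rng = np.random.default_rng(seed)

    g = np.zeros(panel.n_samples)
    causal_ids: list[str] = []
    effects = np.zeros(0)
    if arch.n_causal > 0 and arch.h2 > 0:
        idx = np.sort(rng.choice(panel.n_variants, size=arch.n_causal, replace=False))
        dist = arch.effect_dist or (lambda r, k: r.standard_normal(k))
        effects = dist(rng, arch.n_causal)
        raw = panel.dosages[:, idx] @ effects
        sd = raw.std()
        if sd == 0:
            raise ValueError("genetic values are constant; cannot scale to h2")
        scale = np.sqrt(arch.h2) / sd
        g = (raw - raw.mean()) * scale
        effects = effects * scale
        causal_ids = panel.variants["SNP"].iloc[idx].tolist()

    noise_sd = np.sqrt(max(0.0, 1.0 - arch.h2))
    axis = panel.axis_values
    y = g + arch.strat_delta * axis + rng.normal(0.0, noise_sd, panel.n_samples)

    table = pd.DataFrame(
        {
            "sample_id": panel.sample_ids,
            "phenotype": y,
            "age": rng.uniform(20.0, 70.0, panel.n_samples),
            "sex": rng.integers(0, 2, panel.n_samples),
            "axis": axis,
        }
    )
    return table, PhenotypeTruth(causal_ids, effects, g)


def simulate_expression(
    panel: GenotypePanel,
    eqtl_spec: Sequence[tuple[str, str, float]],
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a genes x samples expression matrix with point-mass cis-eQTLs.

    Each (variant id, gene id, slope) entry adds slope * dosage to that gene;
    independent Gaussian noise with sd ``noise_sd`` is added per gene.
    """
    rng = np.random.default_rng(seed)
    snp_index = {s: i for i, s in enumerate(panel.variants["SNP"])}
    genes: dict[str, np.ndarray] = {}
    for vid, gid, slope in eqtl_spec:
        if vid not in snp_index:
            raise KeyError(f"variant {vid!r} not in panel")
        base = genes.setdefault(gid, np.zeros(panel.n_samples))
        genes[gid] = base + slope * panel.dosages[:, snp_index[vid]]
    out = {}
    for gid in genes:
        out[gid] = genes[gid] + (
            rng.normal(0.0, noise_sd, panel.n_samples) if noise_sd > 0 else 0.0
        )
    return pd.DataFrame(out, index=panel.sample_ids).T


def emit_study(
    panel: GenotypePanel,
    phenotypes: pd.DataFrame,
    out_dir: str,
    truth: PhenotypeTruth | None = None,
    seed: int | None = None,
) -> dict[str, str]:
    """Write a study fixture: VCF 4.2 genotypes (GT + DS), phenotype table,
    and a JSON sidecar with ground truth.  Round-trip via :func:`read_study`
    reproduces dosages and phenotypes exactly (hard genotypes bit-exactly;
    fractional dosages at their stored 6-decimal precision)."""
    if panel.n_variants == 0 or panel.n_samples == 0:
        raise ValueError("cannot emit an empty panel")
    os.makedirs(out_dir, exist_ok=True)
    vcf_path = os.path.join(out_dir, "genotypes.vcf")
    pheno_path = os.path.join(out_dir, "phenotypes.tsv")
    truth_path = os.path.join(out_dir, "truth.json")

    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in panel.variants["CHR"].astype(str).unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">\n'
        )
        fh.write('##INFO=<ID=IS,Number=1,Type=Float,Description="Imputation info score">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, rowv in enumerate(panel.variants.itertuples(index=False)):
            ds = panel.dosages[:, j]
            cells = []
            for d in ds:
                hard = int(round(d))
                gt = gt_map.get(hard, "./.")
                cells.append(f"{gt}:{d:.6f}")
            fh.write(
                f"{rowv.CHR}\t{rowv.POS}\t{rowv.SNP}\t{rowv.REF}\t{rowv.ALT}\t.\t"
                f"PASS\tIS={panel.info[j]:.6f}\tGT:DS\t" + "\t".join(cells) + "\n"
            )

    pheno = phenotypes.copy()
    pheno.to_csv(pheno_path, sep="\t", index=False, float_format="%.17g")

    sidecar = {
        "seed": seed,
        "ancestries": {
            lab: {
                "fst": spec.fst,
                "n_samples": spec.n_samples,
                "strat_axis_value": spec.strat_axis_value,
            }
            for lab, spec in panel.ancestries.items()
        },
        "sample_ancestry": panel.sample_ancestry,
        "causal_ids": truth.causal_ids if truth else [],
        "effects": truth.effects.tolist() if truth else [],
    }
    with open(truth_path, "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return {"vcf": vcf_path, "phenotypes": pheno_path, "truth": truth_path}


def read_study(out_dir: str) -> tuple[GenotypePanel, pd.DataFrame, dict]:
    """Read a study fixture written by :func:`emit_study`."""
    from cyvcf2 import VCF

    vcf_path = os.path.join(out_dir, "genotypes.vcf")
    vcf = VCF(vcf_path)
    sample_ids = list(vcf.samples)
    rows, dosage_cols, info_scores = [], [], []
    for rec in vcf:
        rows.append(
            {
                "SNP": rec.ID,
                "CHR": rec.CHROM,
                "POS": rec.POS,
                "REF": rec.REF,
                "ALT": rec.ALT[0],
            }
        )
        ds = np.asarray(rec.format("DS"), dtype=np.float64).ravel()
        # DS is stored to 6 decimals; undo cyvcf2's float32 representation.
        dosage_cols.append(np.round(ds, 6))
        info_scores.append(float(rec.INFO.get("IS", 1.0)))
    vcf.close()
    variants = pd.DataFrame(rows)
    dosages = np.column_stack(dosage_cols) if dosage_cols else np.zeros((len(sample_ids), 0))

    with open(os.path.join(out_dir, "truth.json")) as fh:
        sidecar = json.load(fh)
    ancestries = {
        lab: AncestrySpec(
            label=lab,
            fst=d["fst"],
            n_samples=d["n_samples"],
            strat_axis_value=d["strat_axis_value"],
        )
        for lab, d in sidecar["ancestries"].items()
    }
    panel = GenotypePanel(
        variants=variants,
        dosages=dosages,
        sample_ids=sample_ids,
        sample_ancestry=sidecar["sample_ancestry"],
        ancestries=ancestries,
        info=np.round(np.asarray(info_scores, dtype=float), 6),
    )
    phenotypes = pd.read_csv(os.path.join(out_dir, "phenotypes.tsv"), sep="\t")
    return panel, phenotypes, sidecar
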