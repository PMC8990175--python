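"""Signed LD correlation matrices over variant windows."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simdata import GenotypePanel


@dataclass
class LdMatrix:
    """Signed correlation matrix r over an ordered variant window.

    Symmetric with unit diagonal and |r| <= 1; repaired to positive
    semidefiniteness by eigenvalue clipping when numerical noise pushes an
    eigenvalue below -1e-6.  ``geno_var`` optionally carries the observed
    per-variant genotype variances of the reference panel so summary-based
    reconstructions can match in-sample regression exactly.
    """

    variants: list[str]
    r: np.ndarray
    ref_n: int = 0
    provenance: str = ""
    geno_var: np.ndarray | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.shape != (len(self.variants), len(self.variants)):
            raise ValueError("LD matrix shape does not match variant list")
        if not np.allclose(r, r.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if np.nanmax(np.abs(r)) > 1 + 1e-8:
            raise ValueError("correlations must satisfy |r| <= 1")
        r = (r + r.T) / 2.0
        np.fill_diagonal(r, 1.0)
        w = np.linalg.eigvalsh(r)
        if w.min() < -1e-6:
            r = psd_repair(r)
        self.r = r

    def index_of(self, variant: str) -> int:
        return self.variants.index(variant)

    def submatrix(self, ids: list[str]) -> "LdMatrix":
        idx = [self.index_of(v) for v in ids]
        return LdMatrix(
            variants=list(ids),
            r=self.r[np.ix_(idx, idx)],
            ref_n=self.ref_n,
            provenance=self.provenance,
            geno_var=None if self.geno_var is None else self.geno_var[idx],
        )


def psd_repair(r: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and restore the unit diagonal."""
    w, v = np.linalg.eigh((r + r.T) / 2.0)
    w = np.clip(w, 0.0, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(fixed), 1e-12, None))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def ld_from_panel(panel: GenotypePanel, variant_ids: list[str] | None = None) -> LdMatrix:
    """Empirical signed LD from a genotype panel's dosages."""
    if variant_ids is None:
        variant_ids = panel.variants["SNP"].tolist()
    pos = {s: i for i, s in enumerate(panel.variants["SNP"])}
    idx = [pos[v] for v in variant_ids]
    G = panel.dosages[:, idx]
    sd = G.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("monomorphic variant in LD window")
    r = np.corrcoef(G, rowvar=False)
    r = np.atleast_2d(r)
    return LdMatrix(
        variants=list(variant_ids),
        r=np.clip(r, -1.0, 1.0),
        ref_n=panel.n_samples,
        provenance="panel",
        geno_var=G.var(axis=0, ddof=0),
    )
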