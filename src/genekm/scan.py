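"""Per-gene, per-replicate scanning, Q-Q summaries and power tables."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import ModelSpec
from .score_test import GeneModelTester
from .simulate import ReplicateSet

logger = logging.getLogger(__name__)

__all__ = ["ScanResult", "run_scan", "qq_data", "empirical_power", "band_fraction_inside"]

RESULT_COLUMNS = ["gene_id", "model_id", "replicate", "Q", "kappa", "nu", "p_value", "method"]


@dataclass
class ScanResult:
    """Long table of test results plus provenance."""

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)

    def pvalues(self, gene_id: str, model_id: str) -> np.ndarray:
        t = self.table
        sel = (t["gene_id"] == gene_id) & (t["model_id"] == model_id)
        return t.loc[sel].sort_values("replicate")["p_value"].to_numpy()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ScanResult":
        return cls(table=pd.read_csv(path, sep="\t"))


def run_scan(rs: ReplicateSet, models: list[ModelSpec],
             genes: list[str] | None = None,
             replicates: list[str] | None = None) -> ScanResult:
    """Apply every model to every gene and phenotype replicate.

    The design, kernel and null moments are computed once per
    (gene, model) since genotypes are fixed across replicates.  Per-gene
    failures are recorded and the scan continues.
    """
    gene_ids = genes if genes is not None else rs.gene_ids
    Y = rs.Y if replicates is None else rs.Y[list(replicates)]
    rep_names = list(Y.columns)
    rows = []
    failures = []
    for gene_id in gene_ids:
        G = rs.gene_genotypes(gene_id)
        for model in models:
            try:
                tester = GeneModelTester(model, G, rs.covariates, rs.G_wide, gene_id=gene_id)
                results = tester.test_many(Y.to_numpy(dtype=float))
            except Exception as exc:  # noqa: BLE001 - scan must continue
                logger.error("gene %s model %s failed: %s", gene_id, model.model_id, exc)
                failures.append({"gene_id": gene_id, "model_id": model.model_id,
                                 "error": str(exc)})
                continue
            for rep, res in zip(rep_names, results):
                rows.append((gene_id, model.model_id, rep, res.Q, res.kappa,
                             res.nu, res.p_value, res.method))
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    prov = {
        "n_samples": int(len(rs.Y)),
        "n_replicates": len(rep_names),
        "seed": rs.config.seed,
        "models": [m.model_id for m in models],
    }
    return ScanResult(table=table, provenance=prov, failures=failures)


P_CLIP = 1e-300


def qq_data(pvalues) -> pd.DataFrame:
    """Observed vs expected -log10 p with pointwise 95% null bands.

    The i-th smallest p-value is compared with the Beta(i, m-i+1) order
    statistic: expected = -log10 of its median, band = -log10 of its
    0.975 / 0.025 quantiles (lower / upper on the -log10 scale).
    Columns: rank, p, observed, expected, lower, upper; rank 1 is the
    smallest p-value.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p <= 0) | (p > 1)):
        if np.any(p > 1) or np.any(p < 0):
            raise ValueError("p-values must lie in (0, 1]")
        logger.warning("qq_data: p-values of 0 clipped to %g", P_CLIP)
        p = np.clip(p, P_CLIP, 1.0)
    m = p.size
    p_sorted = np.sort(p)
    i = np.arange(1, m + 1)
    a, b = i, m - i + 1
    expected = -np.log10(stats.beta.median(a, b))
    upper = -np.log10(stats.beta.ppf(0.025, a, b))
    lower = -np.log10(stats.beta.ppf(0.975, a, b))
    return pd.DataFrame({
        "rank": i,
        "p": p_sorted,
        "observed": -np.log10(p_sorted),
        "expected": expected,
        "lower": lower,
        "upper": upper,
    })


def band_fraction_inside(qq: pd.DataFrame) -> float:
    """Fraction of observed points lying inside the pointwise band."""
    inside = (qq["observed"] >= qq["lower"]) & (qq["observed"] <= qq["upper"])
    return float(inside.mean())


def empirical_power(result: ScanResult, alpha: float,
                    truth: dict | None = None) -> pd.DataFrame:
    """Per (gene, model) rejection rate at level alpha with its MC SE."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    t = result.table
    rows = []
    for (gene_id, model_id), sub in t.groupby(["gene_id", "model_id"], sort=False):
        m = len(sub)
        power = float((sub["p_value"] <= alpha).mean())
        se = float(np.sqrt(power * (1.0 - power) / m))
        row = {"gene_id": gene_id, "model_id": model_id, "n_replicates": m,
               "power": power, "mc_se": se}
        if truth is not None:
            row["truth"] = truth.get(gene_id, "unknown")
        rows.append(row)
    return pd.DataFrame(rows)
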