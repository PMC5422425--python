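"""Model/Results interface for the combined hybrid-design association test.

:class:`PopfamModel` wraps a :class:`~popfam.pedigree.HybridDesign` plus a
:class:`~popfam.combine.CombinerConfig`; :meth:`PopfamModel.fit` runs the
full per-SNP pipeline (MAF -> gene-drop null correlation -> component
statistics -> combined quadratic form -> bootstrap p-value, with MAX and
2-df chi-square comparators) and returns a :class:`PopfamResults` carrying a
tidy per-SNP table, a ``summary()`` rendering and TSV export with a
reproducibility header.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .combine import (
    CombinerConfig,
    bootstrap_pvalue,
    chi2_2df_test,
    estimate_null_correlation,
    max_test,
    popfam_statistic,
)
from .components import ComponentEngine, DegenerateSnpError, estimate_maf
from .pedigree import HybridDesign, KinshipMatrix, kinship_matrix, read_ped

__all__ = ["PopfamModel", "PopfamResults"]

_COLUMNS = [
    "snp_id", "p_hat", "maf_source", "x", "y", "rho_hat", "statistic",
    "p_value", "p_wqls", "p_pdt", "p_max", "p_chi2",
    "n_informative_families", "n_used_pop", "n_gene_drops_used", "reason",
]


class PopfamModel:
    """Combined family + population association test on a hybrid design.

    Parameters
    ----------
    design
        Validated pedigree/genotype container (families, controls, optional
        independent cases identified by role labels).
    config
        Combiner configuration (tau, replicate counts, seed, MAF source).
    kin
        Optional precomputed kinship matrix; computed from the pedigree
        otherwise.
    """

    def __init__(
        self,
        design: HybridDesign,
        config: CombinerConfig | None = None,
        kin: KinshipMatrix | None = None,
    ):
        self.design = design
        self.config = config or CombinerConfig()
        self.kin = kin if kin is not None else kinship_matrix(design)

    @classmethod
    def from_ped(
        cls,
        ped_path: str | Path,
        map_path: str | Path,
        roles: str | Path | dict | None = None,
        config: CombinerConfig | None = None,
    ) -> "PopfamModel":
        """Build a model straight from PED/MAP (+ roles sidecar) files."""
        return cls(read_ped(ped_path, map_path, roles), config)

    def fit(self, snp_ids: list[str] | None = None) -> "PopfamResults":
        """Run the per-SNP pipeline for every (or the given) SNPs.

        Undefined statistics never raise: the affected row carries ``NaN``
        values and a ``reason``. Deterministic given ``config.seed``; each
        SNP gets an independent child RNG stream.
        """
        cfg = self.config
        ids = snp_ids if snp_ids is not None else self.design.snp_ids
        root = np.random.SeedSequence(cfg.seed)
        streams = root.spawn(len(ids))
        rows = []
        for snp_id, ss in zip(ids, streams):
            rows.append(self._fit_one(snp_id, np.random.default_rng(ss)))
        table = pd.DataFrame(rows, columns=_COLUMNS)
        return PopfamResults(model=self, table=table)

    def _fit_one(self, snp_id: str, rng: np.random.Generator) -> dict:
        cfg = self.config
        row = {c: np.nan for c in _COLUMNS}
        row.update(snp_id=snp_id, reason="", maf_source=cfg.maf_source)
        try:
            maf = estimate_maf(self.design, snp_id, cfg.maf_source)
        except DegenerateSnpError:
            maf = None
        if maf is None or not 0.0 < maf.p_hat < 1.0:
            # spec'd fallback: a monomorphic/empty source cannot drive gene
            # dropping; retry on all samples before declaring the SNP degenerate
            if cfg.maf_source != "all":
                try:
                    maf = estimate_maf(self.design, snp_id, "all")
                    row["maf_source"] = "all"
                except DegenerateSnpError:
                    maf = None
        if maf is None or not 0.0 < maf.p_hat < 1.0:
            row["reason"] = "degenerate MAF"
            if maf is not None:
                row["p_hat"] = maf.p_hat
            return row
        row["p_hat"] = maf.p_hat

        s = self.design.snp_index(snp_id)
        try:
            engine = ComponentEngine(self.design, self.kin, s)
        except DegenerateSnpError as e:
            row["reason"] = str(e)
            return row
        counts = self.design.genotypes[s].counts.copy()
        counts[np.isnan(counts)] = 0.0  # engine only reads non-missing slots
        x_arr, y_arr = engine.compute(counts[:, None])
        x, y = float(x_arr[0]), float(y_arr[0])
        row.update(
            x=x, y=y,
            n_informative_families=engine.pdt_informative_families(counts),
            n_used_pop=engine.n_used_pop,
        )
        if not np.isfinite(x) or not np.isfinite(y):
            row["reason"] = ("wQLS undefined" if not np.isfinite(x) else "PDT undefined")
            if np.isfinite(x):
                row["p_wqls"] = 2.0 * stats.norm.sf(abs(x))
            if np.isfinite(y):
                row["p_pdt"] = 2.0 * stats.norm.sf(abs(y))
            return row

        try:
            drop = estimate_null_correlation(
                self.design, self.kin, snp_id, maf, cfg, rng=rng, engine=engine
            )
        except ValueError as e:
            row["reason"] = f"gene drop failed: {e}"
            return row
        rho = drop.rho_hat
        q = popfam_statistic(x, y, rho, cfg.tau)
        row.update(
            rho_hat=rho,
            statistic=q,
            n_gene_drops_used=drop.n_used,
            p_value=bootstrap_pvalue(x, y, rho, cfg.tau, cfg.n_bootstrap, rng),
            p_wqls=2.0 * stats.norm.sf(abs(x)),
            p_pdt=2.0 * stats.norm.sf(abs(y)),
            p_max=max_test(x, y, rho, cfg.n_bootstrap, rng),
            p_chi2=chi2_2df_test(x, y),
        )
        return row


@dataclass
class PopfamResults:
    """Per-SNP results of a fitted :class:`PopfamModel`.

    ``table`` columns: snp_id, p_hat, maf_source, x (signed-root wQLS),
    y (PDT), rho_hat, statistic, p_value (combined, bootstrap), p_wqls,
    p_pdt, p_max, p_chi2, n_informative_families, n_used_pop,
    n_gene_drops_used, reason.
    """

    model: PopfamModel
    table: pd.DataFrame

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Combined hybrid-design association test",
            f"  individuals: {self.model.design.n_individuals}  "
            f"families: {len(self.model.design.families)}  SNPs: {len(self.table)}",
            f"  tau={cfg.tau}  gene drops={cfg.n_gene_drops}  "
            f"bootstrap={cfg.n_bootstrap}  seed={cfg.seed}  maf_source={cfg.maf_source}",
            "",
        ]
        cols = ["snp_id", "p_hat", "x", "y", "rho_hat", "statistic",
                "p_value", "p_wqls", "p_pdt", "p_max", "p_chi2"]
        lines.append(self.table[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        failed = self.table[self.table["reason"] != ""]
        if len(failed):
            lines.append("")
            lines.append(f"  {len(failed)} SNP(s) not fully evaluated:")
            for _, r in failed.iterrows():
                lines.append(f"    {r['snp_id']}: {r['reason']}")
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        """Write the per-SNP table with a reproducibility header."""
        cfg = self.model.config
        with open(path, "w") as fh:
            fh.write(f"# popfam {__version__}\n")
            fh.write(
                f"# tau={cfg.tau} n_gene_drops={cfg.n_gene_drops} "
                f"n_bootstrap={cfg.n_bootstrap} seed={cfg.seed} "
                f"maf_source={cfg.maf_source}\n"
            )
            self.table.to_csv(fh, sep="\t", index=False)

    def gene_minp(self, snp_to_gene: dict[str, str]) -> pd.DataFrame:
        """Minimum p-value per gene across its SNPs, for every test."""
        t = self.table.copy()
        t["gene"] = t["snp_id"].map(snp_to_gene)
        t = t.dropna(subset=["gene"])
        agg = t.groupby("gene").agg(
            n_snps=("snp_id", "size"),
            min_p_popfam=("p_value", "min"),
            min_p_wqls=("p_wqls", "min"),
            min_p_pdt=("p_pdt", "min"),
        )
        return agg.sort_values("min_p_popfam").reset_index()
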