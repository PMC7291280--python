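"""Toxicity-modifier calling from Bar-seq count matrices.

The statistic is deliberately simple and fully relative.  Raw barcode
counts c[s, k] (strain s, kinase experiment k) are first rescaled within
each experiment,

    r[s, k] = c[s, k] / mean_s' c[s', k],

so that sequencing depth cancels and the per-experiment mean of r is 1.
Each strain's rescaled profile is then standardized across the kinase
experiments,

    Z[s, k] = (r[s, k] - mu_s) / sigma_s,

where mu_s and sigma_s are the mean and standard deviation of r[s, ·] over
experiments.  A strain whose relative abundance under one kinase is
unusually high compared with its own behaviour across all kinases is a
toxicity suppressor (Z > tau, default tau = 1.96); unusually low, a
toxicity enhancer (Z < -tau).  Both inequalities are strict.

The model/results split follows the usual fitting idiom: build a
:class:`ModifierScreen` from a count matrix, call :meth:`~ModifierScreen.fit`,
and read estimates off the returned :class:`ModifierScreenResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import BarcodeCatalog
from .demux import CountMatrix

SUPPRESSOR = "suppressor"
ENHANCER = "enhancer"
NON_MODIFIER = "non_modifier"

DEFAULT_TAU = 1.96


@dataclass(frozen=True)
class CallingParams:
    """Thresholding parameters for modifier calls.

    tau : Z-score cutoff; suppressors have Z > tau, enhancers Z < -tau
        (strict inequalities, so Z == tau is a non-modifier).
    sd_mode : 'sample' (n-1 denominator, default) or 'population' for the
        across-experiment standard deviation.
    """

    tau: float = DEFAULT_TAU
    sd_mode: str = "sample"

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.sd_mode not in ("sample", "population"):
            raise ValueError("sd_mode must be 'sample' or 'population'")

    @property
    def ddof(self) -> int:
        return 1 if self.sd_mode == "sample" else 0


def _as_frame(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    if isinstance(counts, CountMatrix):
        return counts.counts
    return counts


def rescale(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Divide each count by its experiment's mean count over strains.

    An all-zero experiment column would divide by zero; it is returned as
    zeros with a warning, since it carries no abundance information.
    """
    df = _as_frame(counts).astype(float)
    if df.empty:
        raise ValueError("count matrix is empty")
    col_means = df.mean(axis=0)
    zero_cols = col_means[col_means == 0].index
    if len(zero_cols):
        warnings.warn(
            f"experiments with zero total counts rescaled to 0: {list(zero_cols)}"
        )
        col_means = col_means.replace(0, np.nan)
    r = df.div(col_means, axis=1)
    return r.fillna(0.0)


def zscores(
    rescaled: pd.DataFrame, params: CallingParams = CallingParams()
) -> tuple[pd.DataFrame, pd.Series, pd.Series, pd.Series]:
    """Standardize each strain's rescaled profile across experiments.

    Returns (Z, mu, sigma, degenerate).  Strains with zero across-experiment
    variance (sigma == 0) get Z ≡ 0 and are flagged degenerate rather than
    dropped, keeping matrix shapes stable.
    """
    if rescaled.shape[1] < 2:
        raise ValueError(
            "Z-scores need at least 2 kinase experiments to estimate the "
            "across-experiment standard deviation"
        )
    mu = rescaled.mean(axis=1)
    sigma = rescaled.std(axis=1, ddof=params.ddof)
    degenerate = sigma == 0
    safe_sigma = sigma.replace(0, np.nan)
    z = rescaled.sub(mu, axis=0).div(safe_sigma, axis=0)
    z.loc[degenerate] = 0.0
    return z, mu, sigma, degenerate


def call_modifiers(
    z: pd.DataFrame,
    params: CallingParams = CallingParams(),
    gene_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One modifier call per (strain, kinase) cell of the Z matrix.

    Returns a long DataFrame with columns strain_id, yeast_gene, kinase, z,
    label.  Strains missing from ``gene_map`` keep their strain_id as gene.
    """
    long = z.stack().rename("z").reset_index()
    long.columns = ["strain_id", "kinase", "z"]
    label = np.where(
        long["z"].values > params.tau,
        SUPPRESSOR,
        np.where(long["z"].values < -params.tau, ENHANCER, NON_MODIFIER),
    )
    long["label"] = label
    gene_map = gene_map or {}
    long.insert(1, "yeast_gene", long["strain_id"].map(lambda s: gene_map.get(s, s)))
    return long


class ModifierScreen:
    """Model of a pooled toxicity-modifier screen.

    Parameters
    ----------
    counts : CountMatrix or DataFrame (strains × kinase experiments)
        Raw barcode counts.  Row index identifies strains, columns identify
        kinase experiments.
    params : CallingParams
        Z threshold and standard-deviation convention.
    catalog : BarcodeCatalog, optional
        Supplies the deleted-ORF annotation for each strain in the calls
        table; without it the strain id doubles as the gene name.
    control_cols : sequence of column names, optional
        Uninduced (glucose) control experiments.  They are rescaled for
        inspection but excluded from the across-experiment standardization,
        which is defined over the kinase-induction experiments only.
    """

    def __init__(
        self,
        counts: CountMatrix | pd.DataFrame,
        params: CallingParams = CallingParams(),
        catalog: BarcodeCatalog | None = None,
        control_cols: Sequence[str] = (),
    ):
        df = _as_frame(counts)
        if df.empty:
            raise ValueError("count matrix is empty")
        unknown = [c for c in control_cols if c not in df.columns]
        if unknown:
            raise ValueError(f"control columns not in count matrix: {unknown}")
        self.counts = df
        self.params = params
        self.control_cols = list(control_cols)
        self.kinase_cols = [c for c in df.columns if c not in self.control_cols]
        self._gene_map = (
            {s.strain_id: s.yeast_gene for s in catalog} if catalog is not None else {}
        )

    @classmethod
    def from_count_matrix(
        cls, counts: CountMatrix, catalog: BarcodeCatalog | None = None, **kw
    ) -> "ModifierScreen":
        return cls(counts, catalog=catalog, **kw)

    @classmethod
    def from_tsv(cls, path: str | Path, **kw) -> "ModifierScreen":
        return cls(pd.read_csv(path, sep="\t", index_col="strain_id"), **kw)

    def fit(self) -> "ModifierScreenResults":
        """Rescale, standardize and call modifiers."""
        r_all = rescale(self.counts)
        r = r_all[self.kinase_cols]
        z, mu, sigma, degenerate = zscores(r, self.params)
        calls = call_modifiers(z, self.params, self._gene_map)
        return ModifierScreenResults(
            model=self,
            rescaled=r_all,
            zmatrix=z,
            mu=mu,
            sigma=sigma,
            degenerate=degenerate,
            calls=calls,
        )


@dataclass
class ModifierScreenResults:
    """Fitted quantities of a :class:`ModifierScreen`.

    Attributes
    ----------
    rescaled : DataFrame
        r[s, k], per-experiment mean-1 rescaled counts (controls included).
    zmatrix : DataFrame
        Z[s, k] over kinase-induction experiments.
    mu, sigma : Series
        Per-strain mean and standard deviation of r across experiments.
    degenerate : Series of bool
        Strains with sigma == 0 (Z forced to 0).
    calls : DataFrame
        Long table of per-(strain, kinase) modifier calls.
    """

    model: ModifierScreen
    rescaled: pd.DataFrame
    zmatrix: pd.DataFrame
    mu: pd.Series
    sigma: pd.Series
    degenerate: pd.Series
    calls: pd.DataFrame

    @property
    def tau(self) -> float:
        return self.model.params.tau

    def suppressors(self) -> pd.DataFrame:
        return self.calls[self.calls["label"] == SUPPRESSOR]

    def enhancers(self) -> pd.DataFrame:
        return self.calls[self.calls["label"] == ENHANCER]

    def per_kinase_summary(self) -> pd.DataFrame:
        """Suppressor and enhancer counts per kinase experiment."""
        rows = []
        for kinase in self.zmatrix.columns:
            sub = self.calls[self.calls["kinase"] == kinase]
            rows.append(
                {
                    "kinase": kinase,
                    "n_suppressors": int((sub["label"] == SUPPRESSOR).sum()),
                    "n_enhancers": int((sub["label"] == ENHANCER).sum()),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit summary."""
        n_s, n_k = self.zmatrix.shape
        per_k = self.per_kinase_summary()
        lines = [
            "Toxicity-modifier screen".center(58),
            "=" * 58,
            f"Strains:            {n_s}",
            f"Kinase experiments: {n_k}",
            f"Control columns:    {len(self.model.control_cols)}",
            f"Z threshold (tau):  {self.tau} "
            f"({self.model.params.sd_mode} sd, strict inequalities)",
            f"Degenerate strains: {int(self.degenerate.sum())}",
            f"Suppressor calls:   {int((self.calls['label'] == SUPPRESSOR).sum())}",
            f"Enhancer calls:     {int((self.calls['label'] == ENHANCER).sum())}",
            "-" * 58,
            per_k.to_string(index=False),
        ]
        return "\n".join(lines)

    def zmatrix_to_tsv(self, path: str | Path) -> None:
        self.zmatrix.to_csv(path, sep="\t", index_label="strain_id")

    def calls_to_tsv(self, path: str | Path) -> None:
        self.calls.to_csv(path, sep="\t", index=False)
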