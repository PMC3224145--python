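"""Figures and tables for a duplicate-measurement GWAS comparison.

Produces the standard diagnostics: Q-Q plot of per-SNP t statistics against
their theoretical null, Manhattan plots (overlayable for the two scans),
per-measurement histograms, the bivariate measurement scatter with the
squared-difference histogram, and effect-vs-effect / -logP-vs--logP scatters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .concordance import ConcordanceReport
from .mixed_gwas import GwasResult

__all__ = ["QQData", "qq_data", "render_report"]


@dataclass
class QQData:
    """Paired theoretical and observed quantiles, both ascending."""

    theoretical: np.ndarray
    observed: np.ndarray


def qq_data(
    t_values: np.ndarray | pd.Series,
    reference: str = "normal",
    df: float | None = None,
) -> QQData:
    """Observed t statistics vs reference quantiles at (i - 0.5)/n.

    ``reference`` is ``"normal"`` (standard normal, the large-df limit) or
    ``"t"`` with ``df`` degrees of freedom.
    """
    t = np.asarray(t_values, dtype=float)
    t = t[np.isfinite(t)]
    if len(t) < 10:
        raise ValueError("need at least 10 t values")
    n = len(t)
    probs = (np.arange(1, n + 1) - 0.5) / n
    if reference == "normal":
        theo = stats.norm.ppf(probs)
    elif reference == "t":
        if df is None:
            raise ValueError("reference='t' requires df")
        theo = stats.t.ppf(probs, df)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    return QQData(theoretical=theo, observed=np.sort(t))


def _manhattan_coords(table: pd.DataFrame):
    """Cumulative x coordinate per SNP, chromosome boundaries for ticks."""
    offsets, ticks = {}, {}
    x0 = 0
    for chrom, grp in table.groupby("chrom", sort=False):
        offsets[chrom] = x0 - grp["pos"].min()
        ticks[chrom] = x0 + (grp["pos"].max() - grp["pos"].min()) / 2
        x0 += grp["pos"].max() - grp["pos"].min() + 1_000_000
    x = table["pos"] + table["chrom"].map(offsets)
    return x.to_numpy(), ticks


def _manhattan(ax, results: Sequence[GwasResult], alphas):
    colors = ["black", "red", "dimgrey"]
    base = results[0].table
    x, ticks = _manhattan_coords(base)
    for res, col in zip(results, colors):
        t = res.table
        xr, _ = _manhattan_coords(t)
        ok = t["tested"].to_numpy()
        ax.scatter(
            xr[ok], -np.log10(t.loc[ok, "p"].astype(float)), s=4, c=col,
            label=res.metadata.get("trait", ""), alpha=0.7, linewidths=0,
        )
    for alpha, style in zip(alphas, (":", "--")):
        ax.axhline(-np.log10(alpha), color="steelblue", linestyle=style, lw=0.8)
    ax.set_xticks(list(ticks.values()), list(ticks.keys()), fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} P$")
    ax.legend(fontsize=7, frameon=False)


def render_report(
    results: Sequence[GwasResult],
    outdir: str | Path,
    report: ConcordanceReport | None = None,
    measurements: pd.DataFrame | None = None,
    alphas: Sequence[float] = (0.001, 0.0001),
    fmt: str = "png",
) -> dict:
    """Write the figure/table suite; returns a manifest of files written.

    ``results`` holds one or two scans (two gives overlay Manhattan plus the
    between-scan scatters when ``report`` is supplied); ``measurements`` is
    an animal-indexed frame with columns m1, m2 for the trait-level figures.
    File names are deterministic.
    """
    if not results or all(r.table.empty for r in results):
        raise ValueError("no association results to render")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    def save(fig, name):
        path = outdir / f"{name}.{fmt}"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        manifest[name] = str(path)

    # Manhattan (overlay when two scans supplied)
    fig, ax = plt.subplots(figsize=(9, 3.2), layout="constrained")
    _manhattan(ax, results, alphas)
    save(fig, "manhattan")

    # Q-Q of t statistics, one panel per scan
    fig, axes = plt.subplots(
        1, len(results), figsize=(4 * len(results), 3.6), squeeze=False,
        layout="constrained",
    )
    for ax, res in zip(axes[0], results):
        t = res.table.loc[res.table["tested"], "t"].astype(float)
        qq = qq_data(t)
        ax.scatter(qq.theoretical, qq.observed, s=3, c="black", linewidths=0)
        lim = [min(qq.theoretical.min(), qq.observed.min()),
               max(qq.theoretical.max(), qq.observed.max())]
        ax.plot(lim, lim, c="red", lw=0.8)
        ax.set_xlabel("theoretical quantile")
        ax.set_ylabel("observed t")
        ax.set_title(res.metadata.get("trait", ""), fontsize=9)
    save(fig, "qq")

    if measurements is not None:
        m1 = measurements["m1"].dropna()
        m2 = measurements["m2"].dropna()
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.2), layout="constrained")
        for ax, (m, lab) in zip(axes, ((m1, "measurement 1"), (m2, "measurement 2"))):
            bins = np.arange(m.min() - 0.5, m.max() + 1.5)
            ax.hist(m, bins=bins, color="grey", edgecolor="black", lw=0.3)
            ax.set_xlabel(f"{lab} (mm)")
            ax.set_ylabel("frequency")
        save(fig, "trait_histograms")

        both = measurements[["m1", "m2"]].dropna()
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.2), layout="constrained")
        axes[0].scatter(both["m1"], both["m2"], s=5, c="black", alpha=0.4, linewidths=0)
        axes[0].set_xlabel("measurement 1 (mm)")
        axes[0].set_ylabel("measurement 2 (mm)")
        d2 = (both["m1"] - both["m2"]) ** 2
        axes[1].hist(d2, bins=50, color="grey", edgecolor="black", lw=0.3)
        axes[1].set_xlabel("squared difference (mm$^2$)")
        axes[1].set_ylabel("frequency")
        save(fig, "measurement_divergence")

    if len(results) >= 2:
        t1 = results[0].table.set_index("snp")
        t2 = results[1].table.set_index("snp")
        common = t1.index[t1["tested"]].intersection(t2.index[t2["tested"]])
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.6), layout="constrained")
        axes[0].scatter(t1.loc[common, "b"], t2.loc[common, "b"], s=4, c="black",
                        alpha=0.5, linewidths=0)
        axes[0].set_xlabel("allele effect, scan 1 (mm)")
        axes[0].set_ylabel("allele effect, scan 2 (mm)")
        axes[1].scatter(
            -np.log10(t1.loc[common, "p"].astype(float)),
            -np.log10(t2.loc[common, "p"].astype(float)),
            s=4, c="black", alpha=0.5, linewidths=0,
        )
        axes[1].set_xlabel(r"$-\log_{10} P$, scan 1")
        axes[1].set_ylabel(r"$-\log_{10} P$, scan 2")
        save(fig, "effect_concordance")

    # tables
    for i, res in enumerate(results, start=1):
        name = f"gwas_{res.metadata.get('trait', i)}"
        path = outdir / f"{name}.tsv"
        res.to_tsv(path)
        manifest[name] = str(path)
    if report is not None:
        path = outdir / "concordance.tsv"
        report.to_tsv(path)
        manifest["concordance"] = str(path)
        jpath = outdir / "concordance.json"
        report.to_json(jpath)
        manifest["concordance_json"] = str(jpath)
    return manifest
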