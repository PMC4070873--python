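"""Genomic-context tabulation and resampling enrichment.

Enrichment of a probe signature (enhancer membership, GC content) is
judged against a null of seeded random probe sets of the same size drawn
without replacement from the QC-surviving universe — the measurable
background, not the full array. Empirical p-values use the add-one
estimator, p = (1 + #{null >= observed}) / (1 + n_draws), so p is never 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu, spearmanr

from .models import bh_adjust
from .signature import Signature

GENE_REGION_ORDER = ["TSS200", "TSS1500", "UTR5", "FirstExon", "Body", "UTR3",
                     "intergenic"]
CGI_ORDER = ["island", "n_shore", "s_shore", "n_shelf", "s_shelf", "open_sea"]


@dataclass
class EnrichmentResult:
    observed: float
    null_draws: np.ndarray
    n_draws: int
    seed: int

    @property
    def fold(self) -> float:
        null_mean = float(np.mean(self.null_draws))
        return self.observed / null_mean if null_mean > 0 else np.inf

    @property
    def p_upper(self) -> float:
        return float((1 + np.sum(self.null_draws >= self.observed))
                     / (1 + self.n_draws))

    def to_dict(self) -> dict:
        return {"observed": self.observed, "null_mean": float(np.mean(self.null_draws)),
                "fold": self.fold, "p": self.p_upper,
                "n_draws": self.n_draws, "seed": self.seed}


def tabulate_context(sig: Signature, manifest: pd.DataFrame) -> pd.DataFrame:
    """Counts and fractions of signature probes per CGI category and gene region."""
    if len(sig) == 0:
        raise ValueError("signature is empty; nothing to tabulate")
    ann = manifest.loc[sig.probes]
    rows = []
    for axis, order in (("cgi_relation", CGI_ORDER), ("gene_region", GENE_REGION_ORDER)):
        counts = ann[axis].value_counts()
        for cat in order:
            c = int(counts.get(cat, 0))
            rows.append({"axis": axis, "category": cat,
                         "count": c, "fraction": c / len(sig)})
    return pd.DataFrame(rows)


def _random_sets(rng: np.random.Generator, universe_size: int, k: int,
                 n_draws: int) -> np.ndarray:
    out = np.empty((n_draws, k), dtype=np.intp)
    for i in range(n_draws):
        out[i] = rng.choice(universe_size, size=k, replace=False)
    return out


def enhancer_enrichment(sig: Signature, manifest: pd.DataFrame,
                        n_draws: int = 999, seed: int = 0,
                        universe: pd.Index | None = None) -> EnrichmentResult:
    """Fraction of signature probes on enhancers vs equal-size random probe sets."""
    if n_draws < 100:
        raise ValueError("n_draws must be at least 100")
    universe = manifest.index if universe is None else universe
    flags = manifest.loc[universe, "enhancer"].to_numpy(dtype=bool)
    if not flags.any():
        raise ValueError("no enhancer-flagged probes in the universe")
    k = len(sig)
    if k > len(universe):
        raise ValueError("signature is larger than the universe")
    observed = float(manifest.loc[sig.probes, "enhancer"].mean())
    rng = np.random.default_rng(seed)
    draws = _random_sets(rng, len(universe), k, n_draws)
    null = flags[draws].mean(axis=1)
    return EnrichmentResult(observed=observed, null_draws=null,
                            n_draws=n_draws, seed=seed)


def gc_comparison(sig: Signature, manifest: pd.DataFrame,
                  n_draws: int = 999, seed: int = 0,
                  universe: pd.Index | None = None) -> dict:
    """GC content of signature probes vs a random set and the whole universe.

    Returns summary means plus a two-sided Mann–Whitney test of signature
    GC against non-signature GC.
    """
    universe = manifest.index if universe is None else universe
    gc_all = manifest.loc[universe, "gc_content"]
    gc_sig = manifest.loc[sig.probes, "gc_content"].to_numpy()
    rng = np.random.default_rng(seed)
    draws = _random_sets(rng, len(universe), len(sig), n_draws)
    gc_rand_mean = float(gc_all.to_numpy()[draws].mean())
    rest = gc_all.drop(pd.Index(sig.probes), errors="ignore").to_numpy()
    if np.ptp(gc_all.to_numpy()) == 0:
        warnings.warn("GC content is constant; comparison is uninformative")
        p = 1.0
    else:
        p = float(mannwhitneyu(gc_sig, rest, alternative="two-sided").pvalue)
    return {"signature_mean": float(gc_sig.mean()),
            "random_mean": gc_rand_mean,
            "universe_mean": float(gc_all.mean()),
            "p": p, "n_draws": n_draws, "seed": seed}


def meth_expr_by_context(deltas: pd.Series, expr: pd.DataFrame,
                         manifest: pd.DataFrame, min_genes: int = 10
                         ) -> pd.DataFrame:
    """Spearman correlation of gene-level delta-beta with expression logFC,
    stratified by gene region and CpG-island status.

    ``deltas`` is a per-probe signed delta-beta; ``expr`` has one ``log_fc``
    row per gene symbol. Strata with fewer than ``min_genes`` joinable genes
    are reported with NaN statistics and ``tested=False``.
    """
    ann = pd.DataFrame({
        "gene": manifest["gene_symbol"],
        "region": manifest["gene_region"],
        "cgi": np.where(manifest["cgi_relation"] == "island", "CGI", "non-CGI"),
        "delta": deltas.reindex(manifest.index),
    })
    ann = ann[(ann["gene"] != "") & ann["delta"].notna()]
    ann = ann[ann["gene"].isin(expr.index)]
    if ann.empty:
        raise ValueError("no genes joinable between deltas and expression table")
    rows = []
    for (region, cgi), grp in ann.groupby(["region", "cgi"], sort=True):
        per_gene = grp.groupby("gene")["delta"].mean()
        lfc = expr.loc[per_gene.index, "log_fc"]
        n = len(per_gene)
        if n < min_genes:
            rows.append({"gene_region": region, "cgi_status": cgi, "n_genes": n,
                         "rho": np.nan, "p": np.nan, "tested": False})
            continue
        rho, p = spearmanr(per_gene.to_numpy(), lfc.to_numpy())
        rows.append({"gene_region": region, "cgi_status": cgi, "n_genes": n,
                     "rho": float(rho), "p": float(p), "tested": True})
    return pd.DataFrame(rows)


def read_gmt(path: str) -> dict[str, set[str]]:
    """Gene sets in GMT format: name, description, then tab-separated genes."""
    sets: dict[str, set[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def ora_genesets(sig_genes: set[str], genesets: dict[str, set[str]],
                 universe: set[str]) -> pd.DataFrame:
    """Hypergeometric over-representation of signature genes in each set,
    BH-adjusted across sets. Sets are intersected with the universe first."""
    if not universe:
        raise ValueError("empty gene universe")
    if not genesets:
        raise ValueError("no gene sets supplied")
    sig = sig_genes & universe
    rows = []
    for name, genes in genesets.items():
        genes = genes & universe
        overlap = len(sig & genes)
        p = float(hypergeom.sf(overlap - 1, len(universe), len(sig), len(genes)))
        rows.append({"set": name, "set_size": len(genes), "overlap": overlap,
                     "p": min(p, 1.0)})
    df = pd.DataFrame(rows).set_index("set")
    df["q"] = bh_adjust(df["p"].to_numpy())
    return df
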