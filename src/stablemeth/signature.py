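"""Persistence/consistency signature filters, gene-level overlap, DMR calling.

The persistent treatment signature keeps probes that are significant
(FDR-adjusted q below threshold) at *both* timepoints — during treatment
and after release — with the same delta-beta sign in every cell line at
every timepoint, and with mean |delta-beta| across the (line x timepoint)
strata at least the delta threshold. The fraction signature keeps probes
with a blocked-ANOVA p below threshold and a consistent per-line delta of
at least its own threshold in every cell line.

A DMR is a maximal run of neighbouring signature probes on one chromosome
in which every consecutive pair lies within ``max_gap`` bp, with at least
``min_probes`` members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


@dataclass
class Signature:
    """A set of probes with per-probe direction and the thresholds that made it."""
    name: str
    probes: pd.Index
    direction: pd.Series                 # 'hyper' | 'hypo' per probe
    mean_delta: pd.Series                # signed mean delta-beta per probe
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.direction.index.equals(pd.Index(self.probes)):
            self.direction = self.direction.reindex(self.probes)
        if not self.mean_delta.index.equals(pd.Index(self.probes)):
            self.mean_delta = self.mean_delta.reindex(self.probes)

    def __len__(self) -> int:
        return len(self.probes)

    def genes(self, manifest: pd.DataFrame) -> set[str]:
        """Genes with at least one signature probe annotated to them."""
        sym = manifest.reindex(self.probes)["gene_symbol"]
        return set(sym[sym != ""].unique())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"direction": self.direction,
                             "mean_delta": self.mean_delta})


def _check_universe(a: pd.Index, b: pd.Index) -> None:
    sym_diff = a.symmetric_difference(b)
    if len(sym_diff):
        raise ValueError(f"probe universes differ by {len(sym_diff)} probes")


def build_tgfb_signature(dmp_t4: pd.DataFrame, dmp_t8: pd.DataFrame,
                         deltas: pd.DataFrame,
                         q_max: float = 0.05, delta_min: float = 0.10,
                         per_stratum: bool = False) -> Signature:
    """Persistent treatment signature.

    ``deltas`` holds one signed delta-beta column per (cell line x
    timepoint) stratum (an ``overall`` column, if present, is ignored).
    ``per_stratum=True`` demands |delta| >= delta_min in every stratum
    instead of on the stratum average.
    """
    _check_universe(dmp_t4.index, dmp_t8.index)
    _check_universe(dmp_t4.index, deltas.index)
    strata = [c for c in deltas.columns if c != "overall"]
    d = deltas[strata]

    sig_both = (dmp_t4["q"] < q_max) & (dmp_t8["q"] < q_max)
    signs = np.sign(d.to_numpy())
    same_sign = (np.abs(signs.sum(axis=1)) == len(strata))
    if per_stratum:
        delta_ok = (d.abs() >= delta_min).all(axis=1).to_numpy()
    else:
        delta_ok = d.abs().mean(axis=1).to_numpy() >= delta_min
    keep = sig_both.to_numpy() & same_sign & delta_ok

    probes = dmp_t4.index[keep]
    mean_delta = d.loc[probes].mean(axis=1)
    direction = pd.Series(np.where(mean_delta > 0, "hyper", "hypo"),
                          index=probes)
    return Signature(
        name="tgfb_persistent", probes=probes, direction=direction,
        mean_delta=mean_delta,
        provenance={"q_max": q_max, "delta_min": delta_min,
                    "per_stratum": per_stratum,
                    "required_contrasts": ["T4", "T8"], "strata": strata})


def build_cd133_signature(blocked_p: pd.Series, deltas_per_line: pd.DataFrame,
                          p_max: float = 0.001, delta_min: float = 0.05
                          ) -> Signature:
    """Fraction (CD133 pos vs neg) signature: blocked p below threshold and a
    consistent per-line delta of at least ``delta_min`` in every cell line."""
    _check_universe(blocked_p.index, deltas_per_line.index)
    cols = [c for c in deltas_per_line.columns if c != "overall"]
    d = deltas_per_line[cols]
    signs = np.sign(d.to_numpy())
    same_sign = np.abs(signs.sum(axis=1)) == len(cols)
    delta_ok = (d.abs() >= delta_min).all(axis=1).to_numpy()
    keep = (blocked_p < p_max).to_numpy() & same_sign & delta_ok

    probes = blocked_p.index[keep]
    mean_delta = d.loc[probes].mean(axis=1)
    direction = pd.Series(np.where(mean_delta > 0, "hyper", "hypo"), index=probes)
    return Signature(
        name="cd133", probes=probes, direction=direction, mean_delta=mean_delta,
        provenance={"p_max": p_max, "delta_min": delta_min, "per_line": cols})


def signature_overlap_test(genes_a: set[str], genes_b: set[str],
                           universe: set[str]) -> tuple[int, float]:
    """Overlap size and upper-tail hypergeometric p for two gene sets."""
    if not genes_a <= universe or not genes_b <= universe:
        extra = (genes_a | genes_b) - universe
        raise ValueError(f"{len(extra)} genes outside the universe, "
                         f"e.g. {sorted(extra)[:5]}")
    overlap = len(genes_a & genes_b)
    p = float(hypergeom.sf(overlap - 1, len(universe), len(genes_a), len(genes_b)))
    return overlap, min(p, 1.0)


@dataclass
class DMR:
    """A merged run of neighbouring signature probes."""
    chrom: str
    start: int                   # 0-based half-open for export
    end: int
    n_probes: int
    probe_ids: list[str]
    mean_delta: float
    gene_symbol: str
    distance2tss: int | None
    promoter: bool
    gene_tied: bool = False


def call_dmrs(sig: Signature, manifest: pd.DataFrame,
              max_gap: int = 100, min_probes: int = 2) -> list[DMR]:
    """Merge signature probes into regions.

    Per chromosome, probes are sorted by position and split wherever the
    distance to the previous probe exceeds ``max_gap``; maximal runs with
    at least ``min_probes`` members become DMRs.
    """
    unknown = pd.Index(sig.probes).difference(manifest.index)
    if len(unknown):
        raise ValueError(f"signature probe not in manifest: {unknown[0]!r}")
    ann = manifest.loc[sig.probes, ["chrom", "pos", "gene_symbol", "gene_region"]].copy()
    ann["mean_delta"] = sig.mean_delta
    if "tss_pos" in manifest.columns:
        ann["tss_pos"] = manifest.loc[sig.probes, "tss_pos"]
        ann["strand"] = manifest.loc[sig.probes, "strand"]

    dmrs: list[DMR] = []
    for chrom, grp in ann.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
        for run in np.split(np.arange(len(grp)), breaks):
            if len(run) < min_probes:
                continue
            members = grp.iloc[run]
            dmrs.append(_make_dmr(chrom, members))
    return dmrs


def _make_dmr(chrom: str, members: pd.DataFrame) -> DMR:
    pos = members["pos"].to_numpy()
    start0, end = int(pos.min()) - 1, int(pos.max())
    genes = members["gene_symbol"][members["gene_symbol"] != ""]
    tied = False
    if len(genes):
        counts = genes.value_counts()
        top = counts[counts == counts.max()].index.sort_values()
        gene = top[0]
        tied = len(top) > 1
    else:
        gene = ""
    promoter = members["gene_region"].isin(["TSS200", "TSS1500"]).any()
    dist: int | None = None
    if gene and "tss_pos" in members.columns:
        rows = members[members["gene_symbol"] == gene]
        tss = int(rows["tss_pos"].iloc[0])
        if tss >= 0:
            midpoint = (start0 + 1 + end) // 2
            raw = midpoint - tss
            strand = rows["strand"].iloc[0]
            if strand == "-":
                raw = -raw
            elif strand not in ("+", "-"):
                raw = abs(raw)
            dist = int(raw)
    return DMR(chrom=chrom, start=start0, end=end, n_probes=len(members),
               probe_ids=list(members.index), mean_delta=float(members["mean_delta"].mean()),
               gene_symbol=gene, distance2tss=dist, promoter=promoter, gene_tied=tied)


def dmrs_to_table(dmrs: list[DMR]) -> pd.DataFrame:
    """Region table: CHR, Start, End, #probes, Symbol, Distance2TSS, Promoter."""
    return pd.DataFrame([{
        "CHR": d.chrom, "Start": d.start + 1, "End": d.end,
        "n_probes": d.n_probes, "Symbol": d.gene_symbol,
        "Distance2TSS": d.distance2tss if d.distance2tss is not None else "NA",
        "Promoter": d.promoter, "mean_delta": d.mean_delta,
        "probes": ";".join(d.probe_ids),
    } for d in dmrs])


def dmrs_to_bed(dmrs: list[DMR]) -> pd.DataFrame:
    """BED6: 0-based half-open, score = 1000*|mean delta| clipped to 1000."""
    return pd.DataFrame([{
        "chrom": d.chrom, "chromStart": d.start, "chromEnd": d.end,
        "name": d.gene_symbol or f"dmr_{i + 1}",
        "score": int(min(abs(d.mean_delta) * 1000, 1000)),
        "strand": ".",
    } for i, d in enumerate(dmrs)])
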