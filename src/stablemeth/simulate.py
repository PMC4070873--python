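"""Synthetic HM450-style data with known ground truth.

The generator emulates the salient features of Infinium 450K beta-value
data: a bimodal baseline (most CpGs are either largely unmethylated or
largely methylated), beta-distributed replicate noise, two probe
chemistries with the type II chemistry compressed toward 0.5, additive
batch effects on the M (log-odds) scale, and planted treatment effects
that are persistent, transient or cell-line-specific — plus optional
sorted-fraction (CD133 negative/positive) samples and DMR-like clusters
of neighbouring probes sharing one effect.

Every draw flows through a single seeded generator, so a config is a
complete recipe: the same config yields byte-identical tables.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig

CELL_LINES = ("lineA", "lineB")
TIMEPOINTS = ("T4", "T8")
TREATMENTS = ("control", "TGFB")
CGI_CATEGORIES = ("island", "n_shore", "s_shore", "n_shelf", "s_shelf", "open_sea")
GENE_REGIONS = ("TSS200", "TSS1500", "UTR5", "FirstExon", "Body", "UTR3")
TRUTH_CLASSES = ("null", "persistent", "transient", "line_specific")

_CGI_PROBS = (0.30, 0.10, 0.10, 0.05, 0.05, 0.40)
# mean GC content per CGI category; islands are GC rich, open sea GC poor
_CGI_GC_MEAN = {"island": 0.65, "n_shore": 0.55, "s_shore": 0.55,
                "n_shelf": 0.45, "s_shelf": 0.45, "open_sea": 0.38}
_GENE_REGION_PROBS = (0.15, 0.15, 0.05, 0.10, 0.45, 0.10)

CONDITION_COLUMNS = [f"delta_{line}_{tp}" for line in CELL_LINES for tp in TIMEPOINTS]


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_manifest(config: SimConfig) -> pd.DataFrame:
    """Build a synthetic probe manifest on synthetic chromosomes.

    Positions are strictly increasing within each chromosome; DMR-like
    clusters are runs of 2–6 probes packed within ``cluster_span_bp``.
    Probes not in a cluster are spaced 200–2000 bp apart so that, at the
    default 100 bp merge distance, only planted clusters are mergeable.
    """
    config.validate()
    if config.n_probes < 100:
        raise ConfigError("SimConfig.n_probes: need at least 100 probes to build a manifest")
    rng = _rng(config.seed)
    n = config.n_probes

    n_chrom = 4
    chrom_of = np.repeat(np.arange(n_chrom), math.ceil(n / n_chrom))[:n]
    gaps = rng.integers(200, 2001, size=n)

    cluster_id = np.full(n, -1, dtype=int)
    if config.n_dmr_clusters > 0:
        sizes = rng.integers(2, 7, size=config.n_dmr_clusters)
        # candidate start indices, kept 10 probes apart and off chromosome edges
        grid = np.arange(5, n - 10, 10)
        if len(grid) < config.n_dmr_clusters:
            raise ConfigError("SimConfig.n_dmr_clusters: too many clusters for n_probes")
        starts = np.sort(rng.choice(grid, size=config.n_dmr_clusters, replace=False))
        for cid, (start, size) in enumerate(zip(starts, sizes)):
            idx = np.arange(start, start + size)
            chrom_of[idx] = chrom_of[start]          # keep the cluster on one chromosome
            max_step = max(config.cluster_span_bp // max(size - 1, 1), 2)
            gaps[idx[1:]] = rng.integers(1, max_step + 1, size=size - 1)
            cluster_id[idx] = cid

    pos = np.empty(n, dtype=np.int64)
    for c in range(n_chrom):
        mask = chrom_of == c
        pos[mask] = 1 + np.cumsum(gaps[mask])

    cgi = rng.choice(len(CGI_CATEGORIES), size=n, p=_CGI_PROBS)
    cgi_rel = np.array(CGI_CATEGORIES)[cgi]
    gc = np.clip(np.array([_CGI_GC_MEAN[c] for c in cgi_rel])
                 + rng.normal(0.0, 0.08, size=n), 0.1, 0.9)

    # genes are runs of 1-6 consecutive probes; ~70% of probes fall in a gene
    gene_symbol = np.full(n, "", dtype=object)
    gene_region = np.full(n, "intergenic", dtype=object)
    tss_pos = np.full(n, -1, dtype=np.int64)
    strand = np.full(n, ".", dtype=object)
    gene_counter = 0
    i = 0
    while i < n:
        run = int(rng.integers(1, 7))
        run = min(run, n - i)
        # keep a gene on one chromosome
        while run > 1 and chrom_of[i + run - 1] != chrom_of[i]:
            run -= 1
        if rng.random() < 0.70:
            gene_counter += 1
            name = f"GENE{gene_counter:05d}"
            g_strand = "+" if rng.random() < 0.5 else "-"
            idx = np.arange(i, i + run)
            gene_symbol[idx] = name
            gene_region[idx] = rng.choice(GENE_REGIONS, size=run, p=_GENE_REGION_PROBS)
            tss = pos[idx[0]] - int(rng.integers(0, 500)) if g_strand == "+" \
                else pos[idx[-1]] + int(rng.integers(0, 500))
            tss_pos[idx] = tss
            strand[idx] = g_strand
        i += run

    manifest = pd.DataFrame({
        "probe_id": [f"cg{k:08d}" for k in range(n)],
        "chrom": [f"chr{c + 1}" for c in chrom_of],
        "pos": pos,
        "probe_type": rng.choice(["I", "II"], size=n),
        "gc_content": gc,
        "cgi_relation": cgi_rel,
        "gene_symbol": gene_symbol,
        "gene_region": gene_region,
        "enhancer": rng.random(n) < 0.10,
        "cross_reactive": rng.random(n) < config.frac_cross_reactive,
        "cluster_id": cluster_id,
        "tss_pos": tss_pos,
        "strand": strand,
    }).set_index("probe_id")
    return manifest


def _assign_truth(config: SimConfig, manifest: pd.DataFrame,
                  rng: np.random.Generator) -> pd.DataFrame:
    """Assign truth classes, signed deltas and CD133 deltas per probe."""
    n = len(manifest)
    truth_class = np.full(n, "null", dtype=object)
    sign = np.zeros(n)
    n_pers = round(config.frac_persistent * n)
    n_tran = round(config.frac_transient * n)
    n_line = round(config.frac_line_specific * n)

    cluster_id = manifest["cluster_id"].to_numpy()
    cluster_idx = np.flatnonzero(cluster_id >= 0)
    # clustered probes are persistent with one sign per cluster, so a planted
    # cluster behaves as a coherent DMR
    for cid in np.unique(cluster_id[cluster_idx]):
        idx = np.flatnonzero(cluster_id == cid)
        truth_class[idx] = "persistent"
        sign[idx] = 1.0 if rng.random() < 0.5 else -1.0

    free = np.flatnonzero(truth_class == "null")
    free = rng.permutation(free)
    need_pers = max(n_pers - (truth_class == "persistent").sum(), 0)
    take = {"persistent": need_pers, "transient": n_tran, "line_specific": n_line}
    cursor = 0
    for cls, count in take.items():
        idx = free[cursor:cursor + count]
        truth_class[idx] = cls
        sign[idx] = rng.choice([-1.0, 1.0], size=len(idx))
        cursor += count

    delta = np.zeros((n, 4))  # columns follow CONDITION_COLUMNS
    eff = sign * config.delta_effect
    is_pers = truth_class == "persistent"
    is_tran = truth_class == "transient"
    is_line = truth_class == "line_specific"
    delta[is_pers, :] = eff[is_pers, None]
    # transient: effect at T4 only, both lines (columns 0 and 2)
    delta[is_tran, 0] = eff[is_tran]
    delta[is_tran, 2] = eff[is_tran]
    # line-specific: one random line, both timepoints
    which_line = rng.integers(0, 2, size=n)
    for i in np.flatnonzero(is_line):
        cols = (0, 1) if which_line[i] == 0 else (2, 3)
        delta[i, cols[0]] = eff[i]
        delta[i, cols[1]] = eff[i]

    cd133_delta = np.zeros(n)
    if config.frac_cd133 > 0 or config.cd133_overlap > 0:
        nulls = np.flatnonzero(truth_class == "null")
        n_cd = round(config.frac_cd133 * n)
        pick = rng.choice(nulls, size=min(n_cd, len(nulls)), replace=False)
        cd133_delta[pick] = rng.choice([-1.0, 1.0], size=len(pick)) * config.delta_effect
        pers_idx = np.flatnonzero(is_pers)
        n_ov = round(config.cd133_overlap * len(pers_idx))
        if n_ov > 0:
            pick = rng.choice(pers_idx, size=n_ov, replace=False)
            cd133_delta[pick] = eff[pick]

    truth = pd.DataFrame({"truth_class": truth_class}, index=manifest.index)
    for j, col in enumerate(CONDITION_COLUMNS):
        truth[col] = delta[:, j]
    truth["cd133_delta"] = cd133_delta
    truth["cluster_id"] = cluster_id
    return truth


def _make_sample_sheet(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for tp in TIMEPOINTS:
        for line in CELL_LINES:
            for treat in TREATMENTS:
                for rep in range(1, config.n_samples_per_cell + 1):
                    rows.append({
                        "sample_id": f"{line}_{treat}_{tp}_r{rep}",
                        "cell_line": line, "treatment": treat,
                        "timepoint": tp, "replicate": rep, "fraction": "",
                    })
    for line in CELL_LINES:
        for frac in ("neg", "pos"):
            for rep in range(1, config.n_cd133_replicates + 1):
                rows.append({
                    "sample_id": f"{line}_CD133{frac}_r{rep}",
                    "cell_line": line, "treatment": "control",
                    "timepoint": "T4", "replicate": rep, "fraction": frac,
                })
    sheet = pd.DataFrame(rows).set_index("sample_id")
    # replicate-wise processing runs: replicate r of every condition is
    # hybridized in the same run, so batch is balanced across (and thereby
    # orthogonal to) treatment, cell line and timepoint by design
    sheet["batch"] = [f"batch{(r - 1) % config.n_batches + 1}"
                      for r in sheet["replicate"]]
    return sheet


def _sample_means(config: SimConfig, truth: pd.DataFrame, sheet: pd.DataFrame,
                  rng: np.random.Generator) -> np.ndarray:
    """Per-probe per-sample target methylation means, clipped to (clip, 1-clip)."""
    n = len(truth)
    lo, hi = config.clip, 1.0 - config.clip
    c = config.mode_concentration

    # baseline: bimodal mixture; effect probes start in the mode their planted
    # shift can move away from, so the delta survives clipping
    net_sign = np.sign(truth[CONDITION_COLUMNS].sum(axis=1).to_numpy()
                       + truth["cd133_delta"].to_numpy())
    comp_low = np.where(net_sign == 0, rng.random(n) < 0.5, net_sign > 0)
    mode = np.where(comp_low, config.low_mode, config.high_mode)
    mu_p = np.clip(rng.beta(mode * c, (1.0 - mode) * c), lo, hi)

    delta = truth[CONDITION_COLUMNS].to_numpy()
    col_of = {(line, tp): j for j, (line, tp) in enumerate(
        [(line, tp) for line in CELL_LINES for tp in TIMEPOINTS])}

    means = np.empty((n, len(sheet)))
    for s, (sid, row) in enumerate(sheet.iterrows()):
        shift = np.zeros(n)
        if row["fraction"] == "pos":
            shift = truth["cd133_delta"].to_numpy()
        elif row["fraction"] == "" and row["treatment"] == "TGFB":
            shift = delta[:, col_of[(row["cell_line"], row["timepoint"])]]
        means[:, s] = np.clip(mu_p + shift, lo, hi)
    return means


def generate_dataset(config: SimConfig, manifest: pd.DataFrame
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Simulate beta values with companions for a manifest built from the same config.

    Returns ``(beta, sample_sheet, truth, companions)`` where companions holds
    the ``detection_p`` and ``bead_count`` matrices.
    """
    config.validate()
    if len(manifest) != config.n_probes:
        raise ConfigError("manifest does not match config (n_probes differs)")
    rng = _rng(config.seed + 1)

    truth = _assign_truth(config, manifest, rng)
    sheet = _make_sample_sheet(config, rng)
    means = _sample_means(config, truth, sheet, rng)

    if math.isinf(config.noise_precision):
        beta = means.copy()
    else:
        phi = config.noise_precision
        beta = rng.beta(means * phi, (1.0 - means) * phi)

    if config.batch_sd > 0:
        batch_codes = pd.Categorical(sheet["batch"]).codes
        shifts = rng.normal(0.0, config.batch_sd,
                            size=(len(manifest), config.n_batches))
        eps = 1e-6
        b = np.clip(beta, eps, 1 - eps)
        m = np.log2(b / (1 - b)) + shifts[:, batch_codes]
        beta = 1.0 / (1.0 + 2.0 ** (-m))

    type2 = (manifest["probe_type"] == "II").to_numpy()
    if config.type2_distortion > 1.0:
        beta[type2, :] = 0.5 + (beta[type2, :] - 0.5) / config.type2_distortion

    beta = np.clip(beta, 1e-6, 1 - 1e-6)
    beta_df = pd.DataFrame(beta, index=manifest.index, columns=sheet.index)
    detp = pd.DataFrame(rng.random((len(manifest), len(sheet))) * 0.01,
                        index=manifest.index, columns=sheet.index)
    beads = pd.DataFrame(10 + rng.poisson(5.0, size=(len(manifest), len(sheet))),
                         index=manifest.index, columns=sheet.index)
    return beta_df, sheet, truth, {"detection_p": detp, "bead_count": beads}


def generate_expression(truth: pd.DataFrame, manifest: pd.DataFrame,
                        coupling: float, seed: int,
                        noise_sd: float = 0.5, scale: float = 10.0,
                        promoter_mode: str = "null") -> pd.DataFrame:
    """Gene-level log2 fold-changes coupled to planted gene-body methylation.

    For genes with gene-body probes, logFC = coupling * scale * (mean planted
    delta over body probes) + Gaussian noise. Genes with only promoter probes
    get no coupling (``promoter_mode='null'``) or the opposite sign
    (``promoter_mode='anti'``). One row per gene symbol.
    """
    if not -1.0 <= coupling <= 1.0:
        raise ConfigError("coupling must be in [-1, 1]")
    if promoter_mode not in ("null", "anti"):
        raise ConfigError("promoter_mode must be 'null' or 'anti'")
    rng = _rng(seed)
    mean_delta = truth[CONDITION_COLUMNS].mean(axis=1)
    ann = pd.DataFrame({
        "gene": manifest["gene_symbol"],
        "region": manifest["gene_region"],
        "delta": mean_delta,
    })
    ann = ann[ann["gene"] != ""]
    rows = []
    for gene, grp in ann.groupby("gene", sort=True):
        body = grp[grp["region"] == "Body"]
        promoter = grp[grp["region"].isin(["TSS200", "TSS1500"])]
        signal = 0.0
        if len(body):
            signal = coupling * scale * body["delta"].mean()
        elif len(promoter) and promoter_mode == "anti":
            signal = -coupling * scale * promoter["delta"].mean()
        lfc = signal + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        rows.append({"gene_symbol": gene, "log_fc": lfc})
    return pd.DataFrame(rows).set_index("gene_symbol")
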