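"""Tabular input/output and probe-level quality control.

All tables are tab-separated UTF-8 with a mandatory header row, '.' as the
decimal separator and ``NA`` as the missing-value token. Matrices carry the
probe id in the first column and sample ids in the header.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NA_TOKEN = "NA"

MANIFEST_COLUMNS = ["chrom", "pos", "probe_type", "gc_content", "cgi_relation",
                    "gene_symbol", "gene_region", "enhancer", "cross_reactive"]
SHEET_COLUMNS = ["cell_line", "treatment", "timepoint", "replicate", "batch", "fraction"]


class SchemaError(ValueError):
    """A required column is missing or a value violates the schema."""


class ConsistencyError(ValueError):
    """Cross-table identifiers do not line up."""


def write_table(df: pd.DataFrame, path: str, index_label: str = "probe_id") -> None:
    df.to_csv(path, sep="\t", na_rep=NA_TOKEN, index_label=index_label,
              float_format="%.12g")


def read_matrix(path: str, value_range: tuple[float, float] | None = (0.0, 1.0),
                name: str = "beta") -> pd.DataFrame:
    """Read a probes-by-samples numeric matrix, validating the value range."""
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise SchemaError(f"{name} matrix has duplicate probe ids, e.g. {dup}")
    if df.columns.has_duplicates:
        raise SchemaError(f"{name} matrix has duplicate sample ids")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{name} matrix contains non-numeric values: {exc}") from exc
    if value_range is not None:
        lo, hi = value_range
        bad = (df < lo) | (df > hi)
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise SchemaError(
                f"{name} matrix value out of [{lo}, {hi}] at probe "
                f"{df.index[r]!r}, sample {df.columns[c]!r}: {df.iat[r, c]}")
    return df


def read_manifest(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], index_col=0,
                     keep_default_na=False, dtype={"gene_symbol": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"manifest is missing required columns: {missing}")
    df["pos"] = df["pos"].astype(np.int64)
    df["gc_content"] = df["gc_content"].astype(float)
    for col in ("enhancer", "cross_reactive"):
        df[col] = df[col].astype(str).str.lower().isin(["true", "1"])
    df["gene_symbol"] = df["gene_symbol"].fillna("").astype(str)
    dup = df.duplicated(subset=["chrom", "pos"])
    if dup.any():
        raise SchemaError(f"manifest has {int(dup.sum())} probes sharing (chrom, pos)")
    empty = df["gene_symbol"] == ""
    inter = df["gene_region"] == "intergenic"
    if (empty != inter).any():
        n = int((empty != inter).sum())
        raise SchemaError(f"{n} probes violate gene_region='intergenic' iff empty gene_symbol")
    return df


def read_sample_sheet(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"sample sheet is missing required columns: {missing}")
    df["fraction"] = df["fraction"].replace({NA_TOKEN: ""}).astype(str)
    return df


def load_tables(manifest_path: str, beta_path: str, sheet_path: str,
                detp_path: str | None = None, beads_path: str | None = None
                ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, pd.DataFrame]]:
    """Load and cross-validate the manifest, beta matrix and sample sheet."""
    manifest = read_manifest(manifest_path)
    beta = read_matrix(beta_path, (0.0, 1.0), "beta")
    sheet = read_sample_sheet(sheet_path)

    if set(beta.columns) != set(sheet.index):
        only_beta = sorted(set(beta.columns) - set(sheet.index))
        only_sheet = sorted(set(sheet.index) - set(beta.columns))
        raise ConsistencyError(
            f"sample ids disagree between beta matrix and sample sheet; "
            f"matrix-only: {only_beta[:5]}, sheet-only: {only_sheet[:5]}")
    sheet = sheet.loc[beta.columns]
    unknown = beta.index.difference(manifest.index)
    if len(unknown):
        raise ConsistencyError(
            f"{len(unknown)} beta probes absent from manifest, e.g. {list(unknown[:5])}")

    companions: dict[str, pd.DataFrame] = {}
    for key, path, rng in (("detection_p", detp_path, (0.0, 1.0)),
                           ("bead_count", beads_path, (0.0, np.inf))):
        if path is not None:
            mat = read_matrix(path, rng, key)
            if mat.shape != beta.shape or not mat.index.equals(beta.index) \
                    or not mat.columns.equals(beta.columns):
                raise ConsistencyError(f"{key} matrix shape/ids do not match beta matrix")
            companions[key] = mat
    return manifest, beta, sheet, companions


@dataclass
class QCReport:
    """Per-reason removal counts; each probe is counted once, under the first
    triggering reason in the fixed order detection -> beads -> cross-reactive."""
    n_input: int
    removed_detection: int = 0
    removed_beads: int = 0
    removed_cross_reactive: int = 0
    reasons: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    @property
    def n_removed(self) -> int:
        return self.removed_detection + self.removed_beads + self.removed_cross_reactive

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed

    def to_dict(self) -> dict[str, int]:
        return {"n_input": self.n_input, "removed_detection": self.removed_detection,
                "removed_beads": self.removed_beads,
                "removed_cross_reactive": self.removed_cross_reactive,
                "n_retained": self.n_retained}


def qc_filter(beta: pd.DataFrame, manifest: pd.DataFrame,
              detection_p: pd.DataFrame | None = None,
              bead_count: pd.DataFrame | None = None,
              detp_threshold: float = 0.05, min_beads: int = 3,
              max_fail_fraction: float = 0.0,
              cross_reactive_ids: set[str] | None = None
              ) -> tuple[pd.DataFrame, QCReport]:
    """Drop low-quality probes.

    A probe is removed when its detection p-value exceeds ``detp_threshold``
    in more than ``max_fail_fraction`` of samples (0 = fail in any sample,
    the strictest reading), when its bead count falls below ``min_beads`` in
    any sample, or when it is flagged cross-reactive (manifest flag, or an
    explicit id set from a published list).
    """
    probes = beta.index
    fail_det = pd.Series(False, index=probes)
    if detection_p is not None:
        frac = (detection_p.loc[probes] > detp_threshold).mean(axis=1)
        fail_det = frac > max_fail_fraction
    fail_beads = pd.Series(False, index=probes)
    if bead_count is not None:
        fail_beads = (bead_count.loc[probes] < min_beads).any(axis=1)
    fail_xr = manifest.reindex(probes)["cross_reactive"].fillna(False).astype(bool)
    if cross_reactive_ids:
        fail_xr = fail_xr | probes.isin(cross_reactive_ids)

    reason = pd.Series("", index=probes, dtype=object)
    reason[fail_xr] = "cross_reactive"
    reason[fail_beads] = "beads"
    reason[fail_det] = "detection"      # last write wins -> highest precedence

    keep = reason == ""
    if not keep.any():
        raise ValueError("qc_filter removed every probe; check thresholds and inputs")
    report = QCReport(
        n_input=len(probes),
        removed_detection=int((reason == "detection").sum()),
        removed_beads=int((reason == "beads").sum()),
        removed_cross_reactive=int((reason == "cross_reactive").sum()),
        reasons=reason[~keep],
    )
    return beta.loc[keep], report
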