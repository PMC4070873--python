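"""Shared fixtures and the in-memory analysis chain used across tests."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stablemeth import (DesignSpec, ModeratedLinearModel, SimConfig,
                        beta_to_m, build_tgfb_signature, estimate_surrogates,
                        generate_dataset, generate_manifest, group_delta_beta,
                        qc_filter)


def run_analysis_chain(cfg: SimConfig, run_sva: bool = True,
                       trend: bool = True, q_max: float = 0.05,
                       delta_min: float = 0.10) -> dict:
    """Simulate -> QC -> M values -> (SVA) -> joint moderated model per
    timepoint -> group delta-betas -> persistent signature.

    This is the differential-analysis core of the pipeline, run in memory
    and without the normalization stages, so tests can exercise the
    statistical chain directly against the simulator's ground truth.
    """
    manifest = generate_manifest(cfg)
    beta, sheet, truth, companions = generate_dataset(cfg, manifest)
    beta, qc_report = qc_filter(beta, manifest,
                                detection_p=companions["detection_p"],
                                bead_count=companions["bead_count"])
    m = beta_to_m(beta)
    spec = DesignSpec(factor="treatment", contrast=("TGFB", "control"),
                      covariates=("cell_line",), per_timepoint_effects=True)
    sv = None
    if run_sva:
        base = spec.build(spec.select_samples(sheet))
        sv = estimate_surrogates(m, base, max_k=5, seed=cfg.seed)
    dmp = {}
    for tp in ("T4", "T8"):
        model = ModeratedLinearModel.from_sample_sheet(m, sheet, spec,
                                                       surrogates=sv,
                                                       timepoint=tp)
        dmp[tp] = model.fit(trend=trend)
    deltas = group_delta_beta(beta, sheet)
    sig = build_tgfb_signature(dmp["T4"].to_frame(), dmp["T8"].to_frame(),
                               deltas, q_max=q_max, delta_min=delta_min)
    return {"manifest": manifest, "beta": beta, "sheet": sheet, "truth": truth,
            "m": m, "dmp": dmp, "deltas": deltas, "signature": sig,
            "qc_report": qc_report, "surrogates": sv}


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated dataset shared by read-only tests."""
    cfg = SimConfig(n_probes=600, seed=0, n_cd133_replicates=2,
                    frac_cd133=0.02, cd133_overlap=0.5)
    manifest = generate_manifest(cfg)
    beta, sheet, truth, companions = generate_dataset(cfg, manifest)
    return {"config": cfg, "manifest": manifest, "beta": beta,
            "sheet": sheet, "truth": truth, "companions": companions}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_m_matrix(n_probes: int = 40, seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A small M matrix plus a matching sample sheet (2 lines x 2 treatments
    x 2 timepoints x 2 replicates) for direct model tests."""
    g = np.random.default_rng(seed)
    rows = []
    for line in ("lineA", "lineB"):
        for treat in ("control", "TGFB"):
            for tp in ("T4", "T8"):
                for rep in (1, 2):
                    rows.append({"sample_id": f"{line}_{treat}_{tp}_r{rep}",
                                 "cell_line": line, "treatment": treat,
                                 "timepoint": tp, "replicate": rep,
                                 "batch": f"batch{rep}", "fraction": ""})
    sheet = pd.DataFrame(rows).set_index("sample_id")
    m = pd.DataFrame(g.normal(0.0, 1.0, size=(n_probes, len(sheet))),
                     index=[f"cg{i:08d}" for i in range(n_probes)],
                     columns=sheet.index)
    return m, sheet
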