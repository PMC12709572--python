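"""Orchestration: generate/load -> indices -> PARAFAC -> kinetics -> association.

One YAML-serializable configuration drives all stages; a single global seed
deterministically derives every stage seed, so a run is a pure function of
(inputs, config, seed).  Stage failures abort with a stage-labelled error;
outputs written before the failure are retained.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assoc as assoc_mod
from . import photokin as pk
from .constants import DEFAULT_INDEX_DEFS, IndexDefinitions, RateConstantTable
from .parafac import EEMCube, Parafac, excise_scatter
from .spectra import compute_indices, rate_light_absorption
from .synthio import (
    CHANNELS,
    SynthConfig,
    SyntheticDataset,
    gen_dataset,
    stage_rng,
)

logger = logging.getLogger("photoxkit")

__all__ = ["PipelineConfig", "RunReport", "PipelineError", "run_pipeline", "recover_oxidants"]


def recover_oxidants(
    dataset: SyntheticDataset, constants: RateConstantTable | None = None
) -> dict:
    """Invert every sample's probe kinetics; returns {sample_id: {channel: OxidantResult}}.

    Requires the dataset's lamp spectrum (for Ra); raises ``ValueError``
    when it is missing.
    """
    if dataset.lamp is None:
        raise ValueError("no lamp photon-flux spectrum available (dependency of Ra)")
    constants = constants or RateConstantTable()
    out: dict = {}
    for sid in dataset.sample_ids():
        ra = rate_light_absorption(dataset.absorbance[sid], dataset.lamp)
        ffa = pk.fit_first_order(dataset.kinetics[(sid, "FFA")]["series"])
        so = pk.singlet_oxygen(ffa, constants, ra, sid)
        benz = dataset.kinetics[(sid, "benzene-phenol")]["series"]
        rfit = pk.fit_formation_rate(benz, precursor_initial_M=benz[0].initial_conc_M)
        oh = pk.hydroxyl(rfit, constants, benz[0].initial_conc_M, ra, sid)
        tmp = pk.fit_first_order(dataset.kinetics[(sid, "TMP")]["series"])
        t_tmp = pk.triplet_tmp(tmp, oh, so, constants, ra, sid)
        t_hdo = pk.triplet_hdo(dataset.hdo_by_conc(sid), constants, ra, sid)
        out[sid] = {r.channel: r for r in (oh, so, t_tmp, t_hdo)}
    return out


class PipelineError(RuntimeError):
    """A stage invariant was violated; carries the failing stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run."""

    dataset_dir: str | None = None  # load an existing dataset directory ...
    synth: SynthConfig = field(default_factory=SynthConfig)  # ... or generate
    seed: int = 0
    out_dir: str = "photoxkit_run"
    parafac_rank: int = 6
    parafac_restarts: int = 10
    parafac_tol: float = 1e-8
    parafac_max_iter: int = 2000
    excise_halfwidths_nm: tuple = (0.0, 0.0)  # (first, second order); 0,0 = lines only
    apply_excision: bool = False
    hix_normalized: bool = False
    rate_constants: dict = field(default_factory=dict)  # overrides
    responses: tuple = ("ln_phi_singlet_oxygen", "ln_phi_triplet_tmp")
    min_samples_for_split: int = 20
    shap_permutations: int = 64
    pdp_features: int = 3  # PDP curves for the top-k important features

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["synth"] = self.synth.to_dict()
        Path(path).write_text(yaml.safe_dump(_plain(d), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "synth" in d and isinstance(d["synth"], dict):
            d["synth"] = SynthConfig.from_dict(d["synth"])
        for k in ("excise_halfwidths_nm", "responses"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return float(obj)
    return obj


@dataclass
class RunReport:
    """Per-stage status, file manifest, and headline result tables."""

    stages: dict = field(default_factory=dict)  # name -> {"status", "warnings"}
    manifest: list = field(default_factory=list)
    tables: dict = field(default_factory=dict)  # name -> DataFrame
    truth_recovery: pd.DataFrame | None = None
    config_echo: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "stages": self.stages,
            "manifest": self.manifest,
            "config": _plain(self.config_echo),
            "truth_recovery": None
            if self.truth_recovery is None
            else self.truth_recovery.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=str))


def _stage_seed(seed: int, name: str) -> int:
    return int(stage_rng(seed, name).integers(2**31))


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages and write the output directory.

    Association modelling runs in CV-only mode below
    ``config.min_samples_for_split`` samples.  When the dataset carries a
    truth table, a truth-vs-recovered comparison is appended to the report.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_echo=asdict(config))
    report.config_echo["synth"] = config.synth.to_dict()

    def record(stage: str, warns: list) -> None:
        report.stages[stage] = {
            "status": "ok",
            "warnings": [str(w.message) for w in warns],
        }
        for w in warns:
            logger.warning("[%s] %s", stage, w.message)

    def emit(path: Path) -> None:
        report.manifest.append(str(path))

    # ----- stage: data ------------------------------------------------
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            if config.dataset_dir:
                dataset = SyntheticDataset.read(config.dataset_dir)
            else:
                dataset = gen_dataset(config.synth, seed=config.seed)
        except Exception as exc:  # noqa: BLE001 - stage-labelled re-raise
            raise PipelineError("data", str(exc)) from exc
    record("data", caught)
    sample_ids = dataset.sample_ids()
    constants = RateConstantTable().replace(**config.rate_constants) if config.rate_constants \
        else RateConstantTable()
    index_defs = IndexDefinitions(hix_normalized=config.hix_normalized) \
        if config.hix_normalized else DEFAULT_INDEX_DEFS

    # ----- stage: indices ---------------------------------------------
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            rows = []
            doc = dict(zip(dataset.samples["sample_id"], dataset.samples["doc_mg_l"]))
            for sid in sample_ids:
                idx = compute_indices(dataset.absorbance[sid], dataset.eems[sid], doc[sid], index_defs)
                rows.append({"sample_id": sid, **idx.as_dict()})
            indices_df = pd.DataFrame(rows)
            indices_df.to_csv(out / "indices.csv", index=False)
            emit(out / "indices.csv")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("indices", str(exc)) from exc
    record("indices", caught)
    report.tables["indices"] = indices_df

    # ----- stage: parafac ---------------------------------------------
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cube = EEMCube.from_eems({sid: dataset.eems[sid] for sid in sample_ids})
            if config.apply_excision:
                cube = excise_scatter(cube, *config.excise_halfwidths_nm)
            result = Parafac(cube, config.parafac_rank).fit(
                n_restarts=config.parafac_restarts,
                tol=config.parafac_tol,
                max_iter=config.parafac_max_iter,
                seed=_stage_seed(config.seed, "parafac"),
            )
            if dataset.library is not None and config.parafac_rank == dataset.library.n_components:
                result.match_components(dataset.library)
            fractions = result.component_fractions()
            frac_out = fractions.copy()
            frac_out.columns = [f"F{i + 1}" for i in range(config.parafac_rank)] + ["undefined"]
            frac_out.to_csv(out / "fractions.csv")
            result.to_json(out / "parafac_model.json")
            emit(out / "fractions.csv")
            emit(out / "parafac_model.json")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("parafac", str(exc)) from exc
    record("parafac", caught)
    report.tables["fractions"] = frac_out

    # ----- stage: photokin --------------------------------------------
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            recovered = recover_oxidants(dataset, constants)
            ox_rows = [
                r.as_dict() for sid in sample_ids for r in recovered[sid].values()
            ]
            oxidants_df = pd.DataFrame(ox_rows)
            oxidants_df.to_csv(out / "oxidants.csv", index=False)
            constants.to_yaml(out / "constants.yaml")
            emit(out / "oxidants.csv")
            emit(out / "constants.yaml")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("photokin", str(exc)) from exc
    record("photokin", caught)
    report.tables["oxidants"] = oxidants_df

    # ----- stage: assoc -----------------------------------------------
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            frac_feats = frac_out.drop(columns=["undefined"]).reset_index()
            table = assoc_mod.build_feature_table(
                dataset.samples, indices_df, frac_feats, oxidants_df
            )
            feat_cols = [c for c in assoc_mod.FEATURE_COLUMNS if c in table.columns]
            resp_cols = [c for c in table.columns if c.startswith("ln_")]
            corr = assoc_mod.spearman_matrix(table, feat_cols + resp_cols)
            corr.to_csv(out / "correlations.csv")
            emit(out / "correlations.csv")
            mlr_reports, gbt_reports = {}, {}
            shap_written = False
            for resp in config.responses:
                if resp not in table.columns or table[resp].dropna().nunique() < 3:
                    continue
                mlr_reports[resp] = assoc_mod.fit_mlr(
                    table, resp, seed=_stage_seed(config.seed, f"mlr:{resp}")
                ).as_dict()
                gbt = assoc_mod.fit_gbt(
                    table,
                    resp,
                    seed=_stage_seed(config.seed, f"gbt:{resp}"),
                    stratify_column="series" if "series" in table.columns else None,
                    min_samples_for_split=config.min_samples_for_split,
                )
                rep = gbt.as_dict()
                rep["importance_impurity"] = assoc_mod.feature_importance(gbt, "impurity").to_dict()
                rep["importance_permutation"] = assoc_mod.feature_importance(
                    gbt, "permutation", seed=_stage_seed(config.seed, f"perm:{resp}")
                ).to_dict()
                gbt_reports[resp] = rep
                if not shap_written:
                    train_df = table.dropna(subset=feat_cols + [resp])
                    shap = assoc_mod.shapley_values(
                        gbt, train_df, n_permutations=config.shap_permutations,
                        seed=_stage_seed(config.seed, f"shap:{resp}"),
                    )
                    shap.values.to_csv(out / "shap_summary.csv")
                    emit(out / "shap_summary.csv")
                    pdp_dir = out / "pdp"
                    pdp_dir.mkdir(exist_ok=True)
                    top = assoc_mod.feature_importance(gbt, "impurity").index[: config.pdp_features]
                    for f in top:
                        curve = assoc_mod.partial_dependence(gbt, train_df, f)
                        curve.to_csv(pdp_dir / f"{f}.csv", index=False)
                        emit(pdp_dir / f"{f}.csv")
                    shap_written = True
            (out / "mlr_report.json").write_text(json.dumps(mlr_reports, indent=1))
            (out / "gbt_report.json").write_text(json.dumps(gbt_reports, indent=1))
            emit(out / "mlr_report.json")
            emit(out / "gbt_report.json")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("assoc", str(exc)) from exc
    record("assoc", caught)
    report.tables["correlations"] = corr.rho

    # ----- truth comparison -------------------------------------------
    if dataset.truth is not None:
        rows = []
        for sid in sample_ids:
            t = dataset.truth[sid]
            for ch in CHANNELS:
                got = oxidants_df[
                    (oxidants_df["sample_id"] == sid) & (oxidants_df["channel"] == ch)
                ]
                phi_rec = float(got["phi"].iloc[0])
                riss_rec = float(got["riss_M"].iloc[0])
                rows.append(
                    {
                        "sample_id": sid,
                        "channel": ch,
                        "phi_truth": t.phi[ch],
                        "phi_recovered": phi_rec,
                        "phi_rel_error": abs(phi_rec - t.phi[ch]) / t.phi[ch]
                        if t.phi[ch] > 0 else np.nan,
                        "riss_truth": t.riss[ch],
                        "riss_recovered": riss_rec,
                        "riss_rel_error": abs(riss_rec - t.riss[ch]) / t.riss[ch]
                        if t.riss[ch] > 0 else np.nan,
                    }
                )
        report.truth_recovery = pd.DataFrame(rows)
        report.truth_recovery.to_csv(out / "truth_recovery.csv", index=False)
        emit(out / "truth_recovery.csv")

    report.to_json(out / "run_report.json")
    emit(out / "run_report.json")
    return report
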