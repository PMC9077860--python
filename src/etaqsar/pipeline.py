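"""Configuration-driven end-to-end orchestration.

``run_all`` sequences the whole workflow — descriptor computation,
pretreatment, k-medoids division, GA/DCV descriptor selection, PLS fit,
validation, applicability domain and Y-randomization — writing every
intermediate artifact plus a reproducibility manifest (seed, config
hash, package version).  Each stage is a pure function of its inputs,
the config and the seed, so reruns are byte-identical apart from
timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .chemio import Molecule, read_activity, read_sdf, read_smiles
from .eta import MODEL_DESCRIPTORS, VALIDATED_DESCRIPTORS, compute_descriptor_table
from .metrics import validate_model, y_randomization
from .pls import dmodx, fit_pls, hotelling_t2, vip, coefficients_and_weights
from .preprocess import (DEFAULT_CORR_CUT, DEFAULT_K, DEFAULT_SD_CUT,
                         DEFAULT_TEST_FRACTION, DescriptorTable, SplitResult,
                         divide, pretreat)
from .select import DcvConfig, dcv_report, run_ga, save_selection_report

log = logging.getLogger("etaqsar")


@dataclass
class RunConfig:
    structures: str = ""
    activity: str = ""
    activity_kind: str = "pLC50"
    out_dir: str = "etaqsar_out"
    sd_cut: float = DEFAULT_SD_CUT
    corr_cut: float = DEFAULT_CORR_CUT
    k: int = DEFAULT_K
    test_fraction: float = DEFAULT_TEST_FRACTION
    seed: int = 0
    n_lv: int = 3
    dcv: DcvConfig = field(default_factory=DcvConfig)
    t2_confidence: float = 0.95
    dmodx_confidence: float = 0.99
    y_rand_perms: int = 100
    top_m: int = 3

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        dcv_raw = raw.pop("dcv", {})
        ga_raw = dcv_raw.pop("ga", {}) if isinstance(dcv_raw, dict) else {}
        cfg = cls(**raw)
        if dcv_raw or ga_raw:
            from .select import GaConfig
            cfg.dcv = DcvConfig(**dcv_raw, ga=GaConfig(**ga_raw))
        cfg.dcv.seed = cfg.seed
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def read_structures(path: str | Path) -> list[Molecule]:
    path = Path(path)
    if path.suffix.lower() in (".sdf", ".sd", ".mol"):
        return read_sdf(path)
    return read_smiles(path)


def descriptor_stage(mols: list[Molecule], out_csv: str | Path | None = None) -> pd.DataFrame:
    table = compute_descriptor_table(mols)
    if out_csv is not None:
        annotated = table.copy()
        annotated.attrs["unvalidated_columns"] = sorted(
            set(table.columns) - VALIDATED_DESCRIPTORS
        )
        annotated.to_csv(out_csv)
    return table


def fit_published_model(
    table: DescriptorTable,
    train_ids: list[str],
    test_ids: list[str],
    descriptors: tuple[str, ...] = MODEL_DESCRIPTORS,
    n_lv: int = 3,
    y_rand_perms: int = 0,
    seed: int = 0,
):
    """Fit the fixed-composition PLS model on a user-supplied split.

    This is the modeling path for a known descriptor subset (e.g. the five
    published model descriptors with 3 LVs): no selection, just PLS fit +
    the full validation battery.  Returns (model, report, weights table).
    """
    train = table.subset_rows(train_ids).subset_columns(list(descriptors))
    test = table.subset_rows(test_ids).subset_columns(list(descriptors))
    model = fit_pls(train.X, train.y, n_lv=n_lv)
    report = validate_model(model, train.X, train.y, test.X, test.y,
                            y_rand_perms=y_rand_perms, seed=seed)
    weights = coefficients_and_weights(model)
    return model, report, weights


def load_reference_table(path: str | Path) -> tuple[DescriptorTable, list[str], list[str]]:
    """Load a published reference table for conformance checking.

    Expected CSV layout: columns ``id``, ``set`` (``train``/``test``),
    ``pLC50`` and one column per model descriptor (``ETA_dEpsilon_D``,
    ``ETA_EtaP_F``, ``ETA_dAlpha_B``, ``ETA_BetaP_s``, ``ETA_dEpsilon_C``).
    Returns the table plus the train and test id lists.
    """
    df = pd.read_csv(path)
    required = {"id", "set", "pLC50", *MODEL_DESCRIPTORS}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reference table missing columns: {sorted(missing)}")
    df["id"] = df["id"].astype(str)
    df = df.set_index("id")
    table = DescriptorTable(df[list(MODEL_DESCRIPTORS)], df["pLC50"])
    sets = df["set"].str.lower()
    train_ids = list(df.index[sets == "train"])
    test_ids = list(df.index[sets == "test"])
    return table, train_ids, test_ids


def run_all(config: RunConfig) -> dict:
    """Execute every stage and write artifacts + manifest under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }

    def _stage(name: str, fn):
        t0 = time.perf_counter()
        log.info("stage %s ...", name)
        try:
            artifact = fn()
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {
            "status": "ok",
            "artifact": str(artifact),
            "seconds": round(time.perf_counter() - t0, 3),
        }
        return artifact

    mols = read_structures(config.structures)
    activity = read_activity(config.activity, value_kind=config.activity_kind)

    def s_descriptors():
        df = descriptor_stage(mols, out / "descriptors.csv")
        return out / "descriptors.csv"
    _stage("descriptors", s_descriptors)
    table = DescriptorTable.from_frames(pd.read_csv(out / "descriptors.csv", index_col="id").rename(index=str), activity)

    def s_pretreat():
        treated, removal_log = pretreat(table, config.sd_cut, config.corr_cut)
        treated.X.to_csv(out / "pretreated.csv")
        (out / "pretreat_log.json").write_text(json.dumps(removal_log, indent=2))
        return out / "pretreated.csv"
    _stage("pretreat", s_pretreat)
    treated = DescriptorTable(pd.read_csv(out / "pretreated.csv", index_col="id").rename(index=str), table.y)

    def s_split():
        sp = divide(treated, k=config.k, test_fraction=config.test_fraction, seed=config.seed)
        sp.to_json(out / "split.json")
        return out / "split.json"
    _stage("split", s_split)
    sp = SplitResult.from_json(out / "split.json")
    train = treated.subset_rows(sp.train_ids)
    test = treated.subset_rows(sp.test_ids)

    config.dcv.seed = config.seed
    def s_select():
        candidates = run_ga(train, config.dcv)
        reports = dcv_report(candidates, train, test, top_m=config.top_m)
        save_selection_report(reports, config.dcv, out / "selection.json")
        return out / "selection.json"
    _stage("select", s_select)
    selection = json.loads((out / "selection.json").read_text())
    best_cols = selection["models"][0]["descriptors"]

    def s_fit():
        model = fit_pls(train.X[best_cols], train.y, n_lv=min(config.n_lv, len(best_cols)))
        model.to_json(out / "model.json")
        coefficients_and_weights(model).to_csv(out / "coefficients.csv")
        vip(model).to_csv(out / "vip.csv")
        return out / "model.json"
    _stage("fit", s_fit)
    model = fit_pls(train.X[best_cols], train.y, n_lv=min(config.n_lv, len(best_cols)))

    def s_validate():
        report = validate_model(model, train.X[best_cols], train.y,
                                test.X[best_cols], test.y)
        report.to_json(out / "validation.json")
        return out / "validation.json"
    _stage("validate", s_validate)

    def s_ad():
        rows = pd.concat([train.X[best_cols], test.X[best_cols]])
        dm = dmodx(model, rows, confidence=config.dmodx_confidence)
        t2 = hotelling_t2(model, rows, confidence=config.t2_confidence,
                          n_components=min(2, model.n_lv))
        ad = pd.DataFrame({
            "DModX": dm.values, "DModX_inside": dm.inside,
            "T2": t2.values, "T2_inside": t2.inside,
        })
        ad.to_csv(out / "ad.csv")
        (out / "ad_limits.json").write_text(json.dumps(
            {"dmodx_critical": dm.critical, "dmodx_confidence": config.dmodx_confidence,
             "t2_critical": t2.critical, "t2_confidence": config.t2_confidence}, indent=2))
        return out / "ad.csv"
    _stage("ad", s_ad)

    def s_randomize():
        yr = y_randomization(train.X[best_cols], train.y, n_lv=model.n_lv,
                             n_perm=config.y_rand_perms, seed=config.seed)
        yr.records.to_csv(out / "y_randomization.csv", index=False)
        (out / "y_randomization.json").write_text(json.dumps(yr.summary(), indent=2))
        return out / "y_randomization.csv"
    _stage("randomize", s_randomize)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
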