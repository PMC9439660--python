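"""End-to-end orchestration: config, cohort I/O, manifests, the demo run.

A run chains the stages in workflow order — synthetic data (optional) →
tissue masking/tiling → tile classifier → classification maps →
signatures → LASSO-Cox scores with cutpoint → survival evaluation — with
every intermediate written to disk and checksummed, so re-running an
identical config reproduces identical artifacts for deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import risk_model, signatures, surv_eval, synthgen, tissue_classifier

__all__ = ["RunConfig", "RunManifest", "read_cohort", "write_report", "run_end_to_end"]


@dataclass
class RunConfig:
    """Everything a reproducible run needs; round-trips through YAML."""

    outdir: str = "histoscore_run"
    seed: int = 0
    tile_side: int = 96
    min_coverage: float = 0.5
    backend: str = "forest"
    top_k: int = 10
    lambda_rule: str = "min"
    cutpoint_bounds: List[float] = field(default_factory=lambda: [0.10, 0.90])
    horizons_months: List[float] = field(default_factory=lambda: [12.0, 36.0, 60.0])
    # synthetic demo sizes
    n_patients: int = 120
    n_tiles_per_class: int = 120
    use_model_maps: bool = True
    cohort_csv: Optional[str] = None  # use an existing cohort instead of simulating

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def content_hash(self) -> str:
        """Hash of the computational parameters (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("outdir")
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    checksums: Dict[str, str]
    timings: Dict[str, float]
    version: str = __version__

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def read_cohort(path: str) -> pd.DataFrame:
    """Validated cohort table: patient_id, slide_id, time > 0, event ∈ {0,1}."""
    if not Path(path).exists():
        raise FileNotFoundError(f"cohort CSV not found: {path}")
    df = pd.read_csv(path)
    required = ["patient_id", "slide_id", "time", "event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing required columns: {missing}")
    bad: List[int] = []
    for i, row in df.iterrows():
        ok = np.isfinite(row["time"]) and row["time"] > 0 and row["event"] in (0, 1)
        if not ok:
            bad.append(int(i))
    if bad:
        raise ValueError(f"malformed cohort rows (0-based): {bad}")
    return df


def write_report(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)


def run_end_to_end(config: RunConfig) -> RunManifest:
    """Run the full synthetic workflow and write all stage outputs.

    Fails fast with the stage name on error; returns the manifest.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    checksums: Dict[str, str] = {}
    timings: Dict[str, float] = {}

    def _stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = _time.perf_counter()
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(_time.perf_counter() - self.t0, 3)
                if exc is not None:
                    raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return _Timer()

    def _register(path: Path) -> None:
        checksums[path.name] = _sha256(path)

    if config.cohort_csv is not None:
        read_cohort(config.cohort_csv)  # validate before any compute

    # --- synthgen -----------------------------------------------------------
    with _stage("synthgen"):
        tiles = synthgen.generate_labeled_tiles(
            config.n_tiles_per_class, config.tile_side, config.seed
        )
        sim = synthgen.SlideSimConfig(tile_side=config.tile_side)
        slides = synthgen.generate_cohort_slides(config.n_patients, config.seed + 1, sim)

    # --- classifier ---------------------------------------------------------
    with _stage("classifier"):
        train, val, test = tissue_classifier.split_dataset(tiles, seed=config.seed)
        model = tissue_classifier.train_classifier(
            train, val,
            tissue_classifier.TrainConfig(
                backend=config.backend, seed=config.seed, tile_side=config.tile_side
            ),
        )
        report = tissue_classifier.evaluate(model, test)
        model.save(str(out / "classifier.pkl"))
        write_report(model.sidecar(), str(out / "classifier.json"))
        write_report(report.to_dict(), str(out / "classifier_eval.json"))
        _register(out / "classifier.json")
        _register(out / "classifier_eval.json")

    # --- maps + signatures --------------------------------------------------
    with _stage("signatures"):
        X = signatures.cohort_signatures(
            slides,
            tile_side=config.tile_side,
            min_coverage=config.min_coverage,
            k=config.top_k,
            model=model if config.use_model_maps else None,
        )
        X.to_csv(out / "signatures.csv", index_label="slide_id")
        _register(out / "signatures.csv")

    # --- cohort -------------------------------------------------------------
    with _stage("cohort"):
        if config.cohort_csv is not None:
            cohort = read_cohort(config.cohort_csv)
        else:
            spec = synthgen.CohortSpec(n_patients=config.n_patients, seed=config.seed + 2)
            cohort = synthgen.simulate_cohort(spec, slides, X=X)
        cohort.to_csv(out / "cohort.csv", index=False)
        _register(out / "cohort.csv")

    # --- risk model ---------------------------------------------------------
    with _stage("risk_model"):
        rng = np.random.default_rng(config.seed + 3)
        n = len(cohort)
        order = rng.permutation(n)
        n_train = int(round(0.7 * n))
        tr_idx, te_idx = order[:n_train], order[n_train:]
        t = cohort["time"].to_numpy()
        e = cohort["event"].to_numpy()

        fit_hs = risk_model.fit_lasso_cox(
            X.iloc[tr_idx], t[tr_idx], e[tr_idx], seed=config.seed
        )
        hs = np.asarray(risk_model.compute_score(fit_hs, X))

        clinical_cols = ["age", "sex_male", "afp_elevated", "alt_elevated",
                         "tumor_number", "tumor_size_cm"]
        have_clinical = all(c in cohort.columns for c in clinical_cols)
        if have_clinical:
            XC = pd.concat(
                [X.reset_index(drop=True), cohort[clinical_cols].reset_index(drop=True)], axis=1
            )
            fit_cs = risk_model.fit_lasso_cox(
                XC.iloc[tr_idx], t[tr_idx], e[tr_idx], seed=config.seed
            )
            cs = np.asarray(risk_model.compute_score(fit_cs, XC))
            fit_cs.save(str(out / "fit_cs.json"))
            _register(out / "fit_cs.json")
        else:
            cs = None

        cut = risk_model.optimal_cutoff(
            hs[tr_idx], t[tr_idx], e[tr_idx],
            quantile_bounds=tuple(config.cutpoint_bounds),
        )
        groups, counts = risk_model.stratify(hs, cut.cutoff)
        fit_hs.save(str(out / "fit_hs.json"))
        _register(out / "fit_hs.json")
        scored = cohort.copy()
        scored["hs"] = hs
        if cs is not None:
            scored["cs"] = cs
        scored["risk_group"] = groups
        scored["split"] = np.where(np.isin(np.arange(n), tr_idx), "train", "test")
        scored.to_csv(out / "cohort_scored.csv", index=False)
        _register(out / "cohort_scored.csv")

    # --- survival evaluation ------------------------------------------------
    with _stage("surv_eval"):
        stat, p = surv_eval.logrank_test(t, e, groups)
        c_train, _ = surv_eval.harrell_c(t[tr_idx], e[tr_idx], hs[tr_idx], ci=False)
        c_test, _ = surv_eval.harrell_c(t[te_idx], e[te_idx], hs[te_idx], ci=False)
        aucs = {}
        for h in config.horizons_months:
            try:
                aucs[str(h)] = surv_eval.td_roc_auc(
                    t[te_idx], e[te_idx], hs[te_idx], h,
                    train_time=t[tr_idx], train_event=e[tr_idx],
                )
            except ValueError:
                aucs[str(h)] = None
        report = {
            "hs_cutoff": cut.cutoff,
            "risk_group_counts": counts,
            "logrank": {"statistic": stat, "p": p},
            "c_index": {"train": c_train, "test": c_test},
            "td_auc_test": aucs,
            "n_nonzero_hs": fit_hs.n_nonzero,
        }
        if cs is not None:
            nri_value, _ = surv_eval.nri(
                cs[te_idx], hs[te_idx], t[te_idx], e[te_idx],
                horizon=min(config.horizons_months), ci=False,
            )
            report["nri_cs_vs_hs"] = nri_value
        write_report(report, str(out / "report.json"))
        _register(out / "report.json")

    manifest = RunManifest(config.content_hash(), checksums, timings)
    write_report(manifest.to_dict(), str(out / "manifest.json"))
    return manifest
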