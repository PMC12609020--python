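"""End-to-end orchestration of the dual-path VAG analysis.

One configuration (YAML) and one seed drive every stage:

``simulate -> preprocess -> decompose -> features -> reconstruct ->
scalogram -> train-svm -> train-cnn -> report``

Each stage reads its inputs from, and writes plain-text outputs (CSV / JSON /
PNG) into, the run directory, so a run is inspectable and resumable stage by
stage.  The configuration is persisted alongside every output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, dfa, emd, features, io, reconstruct, scalogram, synthetic
from .cnn import AugmentationSpec, CnnConfig, train_cv

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = (
    "simulate",
    "preprocess",
    "decompose",
    "features",
    "reconstruct",
    "scalogram",
    "train-svm",
    "train-cnn",
    "report",
)


@dataclass
class RunConfig:
    """All tunables of one pipeline run; defaults follow the reference setup."""

    out: str = "vagdfa_run"
    seed: int = 0
    # synthetic cohort
    n_per_group: int = 8
    fs_hz: float = 4000.0
    n_cycles: int = 10
    cycle_s: float = 3.0
    channels: tuple[str, ...] = ("K1",)
    chain: str = "CKC"
    # EEMD
    noise_ratio: float = 0.01
    ensemble: int = 100
    max_imf: int = 10
    # DFA grid
    n_windows: int = 30
    # reconstruction gates
    alpha_min: float = 0.5
    r2_min: float = 0.9
    # screening / NCA
    screening_alpha: float = 0.05
    nca_cutoff: float = 0.05
    # SVM
    cv_folds: int = 5
    svm_c: float = 1.0
    # scalogram / CNN
    resolution: int = 128
    cnn_epochs: int = 30
    cnn_batch: int = 32
    cnn_variant: str = "a1"
    stages: tuple[str, ...] = STAGES

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("channels", "stages"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _rec_seed(seed: int, name: str) -> int:
    digest = hashlib.sha256(f"{seed}|{name}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % 2**31


def _log(out: Path, event: str, **details) -> None:
    rec = {"event": event, **details}
    with (out / "log.jsonl").open("a") as fh:
        fh.write(json.dumps(rec, default=str) + "\n")


def run_pipeline(config: RunConfig, stages: tuple[str, ...] | None = None) -> Path:
    """Execute the requested stages; returns the run directory."""
    stages = tuple(stages or config.stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps({**asdict(config), "config_hash": config.config_hash()}, indent=1, default=str)
    )

    if "simulate" in stages:
        _stage_simulate(config, out)
    if "preprocess" in stages:
        _stage_preprocess(config, out)
    if "decompose" in stages:
        _stage_decompose(config, out)
    if "features" in stages:
        _stage_features(config, out)
    if "reconstruct" in stages:
        _stage_reconstruct(config, out)
    if "scalogram" in stages:
        _stage_scalogram(config, out)
    if "train-svm" in stages:
        _stage_svm(config, out)
    if "train-cnn" in stages:
        _stage_cnn(config, out)
    if "report" in stages:
        _stage_report(config, out)
    return out


def _stage_simulate(config: RunConfig, out: Path) -> None:
    spec = synthetic.CohortSpec(
        n_per_group=config.n_per_group,
        fs_hz=config.fs_hz,
        n_cycles=config.n_cycles,
        cycle_s=config.cycle_s,
        channels=config.channels,
        chain=config.chain,
        profiles=synthetic.default_profiles(config.fs_hz),
        seed=config.seed,
    )
    recordings, manifest = synthetic.generate_cohort(spec)
    rec_dir = out / "recordings"
    rec_dir.mkdir(exist_ok=True)
    for rec, path in zip(recordings, manifest["path"]):
        np.savetxt(rec_dir / path, rec.samples, fmt="%.9g")
    manifest = manifest.copy()
    manifest["path"] = [str(rec_dir / p) for p in manifest["path"]]
    manifest.to_csv(out / "manifest.csv", index=False)
    _log(out, "simulate", n_recordings=len(recordings))


def _stage_preprocess(config: RunConfig, out: Path) -> None:
    manifest = io.read_manifest(out / "manifest.csv")
    pre_dir = out / "preprocessed"
    pre_dir.mkdir(exist_ok=True)
    for _, row in manifest.iterrows():
        rec = io.read_recording(row["path"], row.to_dict())
        pre = io.preprocess(rec, n_cycles=config.n_cycles)
        io.write_signal(pre_dir / Path(row["path"]).name, pre)
    _log(out, "preprocess", n=len(manifest))


def _iter_preprocessed(out: Path):
    for path in sorted((out / "preprocessed").glob("*.csv")):
        sidecar = json.loads(path.with_suffix(".csv.json").read_text())
        yield path, np.loadtxt(path), sidecar


def _stage_decompose(config: RunConfig, out: Path) -> None:
    imf_dir = out / "imfs"
    imf_dir.mkdir(exist_ok=True)
    for path, x, sidecar in _iter_preprocessed(out):
        seed = _rec_seed(config.seed, path.stem)
        decomp = emd.eemd(
            x,
            noise_ratio=config.noise_ratio,
            ensemble=config.ensemble,
            max_imf=config.max_imf,
            seed=seed,
        )
        matrix = np.vstack(decomp.imfs + [decomp.residue])
        np.savetxt(imf_dir / path.name, matrix, fmt="%.7g")
        params = {
            "noise_ratio": config.noise_ratio,
            "ensemble": config.ensemble,
            "max_imf": config.max_imf,
            "seed": seed,
            "cycle_len": sidecar["cycle_len"],
            "fs_hz": sidecar["fs_hz"],
            "group": sidecar["group"],
            "subject_id": sidecar["subject_id"],
            "channel": sidecar["channel"],
        }
        (imf_dir / (path.stem + ".json")).write_text(json.dumps(params, indent=1))
    _log(out, "decompose")


def _iter_decompositions(out: Path):
    for path in sorted((out / "imfs").glob("*.csv")):
        params = json.loads(path.with_suffix(".json").read_text())
        matrix = np.loadtxt(path)
        imfs = [matrix[i] for i in range(matrix.shape[0] - 1)]
        decomp = emd.ImfDecomposition(
            imfs=imfs,
            residue=matrix[-1],
            noise_ratio=params["noise_ratio"],
            ensemble=params["ensemble"],
            max_imf=params["max_imf"],
            seed=params["seed"],
        )
        yield path, decomp, params


def _stage_features(config: RunConfig, out: Path) -> None:
    dfa_rows, table_input = [], []
    for path, decomp, params in _iter_decompositions(out):
        fits = dfa.dfa_dual_per_imf(decomp, params["cycle_len"])
        rows = features.imf_feature_rows(decomp, params["fs_hz"])
        for i, fit in enumerate(fits, start=1):
            if fit is None:
                continue
            dfa_rows.append(
                {
                    "recording": path.stem,
                    "imf_index": i,
                    "alpha1": fit.alpha1,
                    "alpha2": fit.alpha2,
                    "r2_1": fit.r2_1,
                    "r2_2": fit.r2_2,
                    "bp_scale_samples": fit.bp_scale,
                    "bp_ratio": fit.bp_ratio,
                }
            )
        meta = {
            "recording": path.stem,
            "subject_id": params["subject_id"],
            "group": params["group"],
            "channel": params["channel"],
        }
        table_input.append((meta, rows, fits))
    pd.DataFrame(dfa_rows).to_csv(out / "dfa_report.csv", index=False)
    features.build_feature_table(table_input).to_csv(out / "features.csv", index=False)
    _log(out, "features", n=len(table_input))


def _stage_reconstruct(config: RunConfig, out: Path) -> None:
    rec_dir = out / "reconstructed"
    rec_dir.mkdir(exist_ok=True)
    report = []
    for path, decomp, params in _iter_decompositions(out):
        fits = dfa.dfa_dual_per_imf(decomp, params["cycle_len"])
        pair = reconstruct.reconstruct_pair(decomp, fits, config.alpha_min, config.r2_min)
        np.savetxt(rec_dir / f"{path.stem}_a1.csv", pair.x_alpha1, fmt="%.7g")
        np.savetxt(rec_dir / f"{path.stem}_a2.csv", pair.x_alpha2, fmt="%.7g")
        report.append(
            {
                "recording": path.stem,
                "included_local": sorted(pair.included_local),
                "included_global": sorted(pair.included_global),
                "empty_local": pair.empty_local,
                "empty_global": pair.empty_global,
            }
        )
    pd.DataFrame(report).to_csv(rec_dir / "inclusion_report.csv", index=False)
    _log(out, "reconstruct", n=len(report))


def _stage_scalogram(config: RunConfig, out: Path) -> None:
    grid = scalogram.default_scale_grid(config.fs_hz)
    img_dir = out / "scalograms"
    img_dir.mkdir(exist_ok=True)
    # group per (group, subject): sum channels for raw and reconstructed variants
    raw: dict[tuple[str, str], list[np.ndarray]] = {}
    rec: dict[tuple[str, str, str], list[np.ndarray]] = {}
    for path, x, sidecar in _iter_preprocessed(out):
        key = (sidecar["group"], sidecar["subject_id"])
        raw.setdefault(key, []).append(x)
        for variant in ("a1", "a2"):
            rpath = out / "reconstructed" / f"{path.stem}_{variant}.csv"
            if rpath.exists():
                rec.setdefault((*key, variant), []).append(np.loadtxt(rpath))
    for (group, subject), signals in raw.items():
        combined = scalogram.combine_channels(*signals)
        m = scalogram.cwt_magnitude(combined, grid)
        img = scalogram.to_rgb_image(
            m, config.resolution, source_id=f"{group}_{subject}", grid_hash=grid.grid_hash
        )
        scalogram.save_png(img, img_dir / f"{group}_{subject}_raw_{config.resolution}.png")
    for (group, subject, variant), signals in rec.items():
        combined = scalogram.combine_channels(*signals)
        m = scalogram.cwt_magnitude(combined, grid)
        img = scalogram.to_rgb_image(
            m, config.resolution, source_id=f"{group}_{subject}", grid_hash=grid.grid_hash
        )
        scalogram.save_png(
            img, img_dir / f"{group}_{subject}_{variant}_{config.resolution}.png"
        )
    _log(out, "scalogram", grid_hash=grid.grid_hash)


def _stage_svm(config: RunConfig, out: Path) -> None:
    table = pd.read_csv(out / "features.csv")
    screening = features.screen_features(
        table, alpha=config.screening_alpha, seed=config.seed
    )
    screening.to_csv(out / "screening.csv", index=False)
    kept_names = list(screening.loc[screening["kept"], "feature"])
    if not kept_names:
        kept_names = list(screening["feature"])
    X = table[kept_names].to_numpy()
    finite = np.all(np.isfinite(X), axis=1)
    X, y = X[finite], table["group"].to_numpy()[finite]
    nca = classify.nca_weights(X, y, seed=config.seed)
    selected = classify.select_by_weight(nca, config.nca_cutoff)
    X_sel = X[:, list(selected)]
    report = classify.svm_rbf_cv(
        X_sel, y, k=config.cv_folds, C=config.svm_c, seed=config.seed
    )
    report.folds.to_csv(out / "svm_folds.csv", index=False)
    np.savetxt(out / "svm_roc.csv", report.roc_points, header="fpr,tpr", comments="")
    summary = {
        "features_screened": kept_names,
        "nca_weights": dict(zip(kept_names, nca.weights.round(4).tolist())),
        "features_selected": [kept_names[i] for i in selected],
        "mean": report.mean,
        "sd": report.sd,
    }
    (out / "svm_summary.json").write_text(json.dumps(summary, indent=1))
    _log(out, "train-svm", **report.mean)


def _stage_cnn(config: RunConfig, out: Path) -> None:
    from PIL import Image

    paths = sorted((out / "scalograms").glob(f"*_{config.cnn_variant}_{config.resolution}.png"))
    if len(paths) < 2 * config.cv_folds:
        raise RuntimeError("not enough scalograms for CNN cross-validation")
    images = np.stack([np.asarray(Image.open(p)) for p in paths])
    labels = np.array([p.name.split("_")[0] for p in paths])
    cnn_config = CnnConfig(
        epochs=config.cnn_epochs, batch=config.cnn_batch, seed=config.seed
    )
    report = train_cv(images, labels, cnn_config, AugmentationSpec(), k=config.cv_folds)
    report.folds.to_csv(out / "cnn_folds.csv", index=False)
    np.savetxt(out / "cnn_roc.csv", report.roc_points, header="fpr,tpr", comments="")
    (out / "cnn_summary.json").write_text(
        json.dumps({"variant": config.cnn_variant, "mean": report.mean, "sd": report.sd}, indent=1)
    )
    _log(out, "train-cnn", **report.mean)


def _stage_report(config: RunConfig, out: Path) -> None:
    summary = {"config_hash": config.config_hash()}
    for name in ("svm_summary.json", "cnn_summary.json"):
        path = out / name
        if path.exists():
            summary[name.removesuffix(".json")] = json.loads(path.read_text())
    (out / "report.json").write_text(json.dumps(summary, indent=1))
    _log(out, "report")
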