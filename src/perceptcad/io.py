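"""Dataset I/O, run configuration and the end-to-end pipeline.

Patches travel as 16-bit PNG pairs (``{case_id}_{view}_img.png`` /
``_mask.png``) referenced from a manifest CSV with one row per view:
``case_id, view, image_path, mask_path``, the five ``*_code`` descriptor
columns, ``label`` and ``split``.  Real FFDM crops stored as DICOM are
ingested transparently when an image path ends in ``.dcm``.

:func:`run_pipeline` orchestrates the whole method end to end — phantom
dataset, K-fold ensemble training on the train split, fused scoring of the
test split, and a model-side ROC evaluation — writing every artifact under
one output directory together with a run summary (seed, config hash,
artifact checksums).  All randomness flows from the single global seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .birads import DESCRIPTOR_FIELDS, DescriptorVector
from .classifier import EnsembleModel, LdaModel, MemberModel, SelectionResult, crossval_train, fused_pom
from .extractor import ExtractorConfig, TrainedExtractor, _build_network
from .mrmc import roc_from_poms
from .phantom import VIEWS, Case, LesionPatch, PhantomConfig, generate_dataset

__all__ = [
    "ManifestError",
    "RunConfig",
    "write_dataset",
    "read_manifest",
    "save_ensemble",
    "load_ensemble",
    "save_extractor",
    "load_extractor",
    "run_pipeline",
]

logger = logging.getLogger("perceptcad")

CODE_COLUMNS = tuple(f"{f}_code" for f in DESCRIPTOR_FIELDS)
MANIFEST_COLUMNS = ("case_id", "view", "image_path", "mask_path", *CODE_COLUMNS, "label")


class ManifestError(ValueError):
    """A structurally invalid manifest (missing columns, files or views)."""


# ---------------------------------------------------------------------------
# patch and manifest I/O
# ---------------------------------------------------------------------------

_PNG_MAX = 65535


def _write_png16(array: np.ndarray, path: Path) -> None:
    data = np.clip(np.asarray(array, dtype=np.float64), 0, 1)
    Image.fromarray((data * _PNG_MAX).round().astype(np.uint16)).save(path)


def _read_image(path: Path) -> np.ndarray:
    if path.suffix.lower() == ".dcm":
        import pydicom

        arr = pydicom.dcmread(str(path)).pixel_array.astype(np.float64)
        lo, hi = arr.min(), arr.max()
        return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    arr = np.asarray(Image.open(path), dtype=np.float64)
    return arr / _PNG_MAX


def write_dataset(cases: list[Case], manifest: pd.DataFrame, out_dir: str | Path) -> Path:
    """Write patches as 16-bit PNG pairs plus ``manifest.csv``; returns its path."""
    out_dir = Path(out_dir)
    patches_dir = out_dir / "patches"
    patches_dir.mkdir(parents=True, exist_ok=True)
    manifest = manifest.copy()
    by_id = {c.case_id: c for c in cases}
    for i, row in manifest.iterrows():
        case = by_id[row["case_id"]]
        patch = case.patches[row["view"]]
        img_path = patches_dir / f"{case.case_id}_{row['view']}_img.png"
        mask_path = patches_dir / f"{case.case_id}_{row['view']}_mask.png"
        _write_png16(patch.image, img_path)
        _write_png16(patch.mask, mask_path)
        manifest.loc[i, "image_path"] = str(img_path.relative_to(out_dir))
        manifest.loc[i, "mask_path"] = str(mask_path.relative_to(out_dir))
    manifest_path = out_dir / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def read_manifest(path: str | Path, strict_two_view: bool = True) -> tuple[list[Case], pd.DataFrame]:
    """Load a manifest CSV into validated two-view cases.

    Rows are grouped by ``case_id``; every case must contribute exactly the
    CC and MLO views unless ``strict_two_view`` is off.  Structural
    problems (missing columns or files, bad descriptor codes, missing
    views) raise :class:`ManifestError` naming the offending rows.
    """
    path = Path(path)
    manifest = pd.read_csv(path)
    missing_cols = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing_cols:
        raise ManifestError(f"manifest missing columns {sorted(missing_cols)}")
    base = path.parent
    errors: list[str] = []
    for col in CODE_COLUMNS:
        bad = ~manifest[col].isin((0.0, 0.5, 1.0))
        if bad.any():
            rows = (manifest.index[bad] + 2).tolist()  # header is line 1
            errors.append(f"{col} outside {{0, 0.5, 1}} at line(s) {rows[:5]}")
    if errors:
        raise ManifestError("; ".join(errors))

    cases: list[Case] = []
    for case_id, grp in manifest.groupby("case_id", sort=False):
        views = sorted(grp["view"])
        if strict_two_view and views != sorted(VIEWS):
            raise ManifestError(f"case {case_id} has views {views}, expected {sorted(VIEWS)}")
        codes = grp[list(CODE_COLUMNS)].drop_duplicates()
        if len(codes) > 1:
            raise ManifestError(f"case {case_id} has inconsistent descriptor codes across views")
        labels = grp["label"].unique()
        if len(labels) > 1:
            raise ManifestError(f"case {case_id} has inconsistent labels across views")
        patches = {}
        for _, row in grp.iterrows():
            for col in ("image_path", "mask_path"):
                if not (base / row[col]).exists():
                    raise ManifestError(
                        f"case {case_id}: file {row[col]!r} not found (line "
                        f"{row.name + 2})"
                    )
            image = _read_image(base / row["image_path"])
            mask = (np.asarray(Image.open(base / row["mask_path"])) > 0).astype(np.uint8)
            patch = LesionPatch(image=image, mask=mask, view=row["view"])
            patch.validate()
            patches[row["view"]] = patch
        case = Case(
            case_id=str(case_id),
            patches=patches,
            descriptors=DescriptorVector.from_array(codes.iloc[0].to_numpy(dtype=float)),
            label=str(labels[0]),
        )
        if strict_two_view:
            case.validate()
        cases.append(case)
    return cases, manifest


# ---------------------------------------------------------------------------
# ensemble persistence
# ---------------------------------------------------------------------------


def save_extractor(model: TrainedExtractor, path: str | Path) -> Path:
    """Save one extractor (config + weights + history) as a single archive."""
    path = Path(path)
    arrays = {
        f"layer{li}_p{pi}": p
        for li, layer in enumerate(model.layers)
        for pi, p in enumerate(layer.params)
    }
    meta = {
        "config": dataclasses.asdict(model.config),
        "history": model.history.to_dict(orient="list"),
        "frozen": model.frozen,
    }
    np.savez_compressed(path, _meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path


def load_extractor(path: str | Path) -> TrainedExtractor:
    data = np.load(Path(path))
    meta = json.loads(bytes(data["_meta"]).decode())
    cfg = meta["config"]
    for key in ("fc_sizes", "lr_decay_epochs"):
        cfg[key] = tuple(cfg[key])
    config = ExtractorConfig(**cfg)
    layers = _build_network(config, np.random.default_rng(config.seed))
    for li, layer in enumerate(layers):
        for pi in range(len(layer.params)):
            layer.params[pi][...] = data[f"layer{li}_p{pi}"]
    model = TrainedExtractor(layers=layers, config=config, history=pd.DataFrame(meta["history"]))
    if meta["frozen"]:
        model.freeze()
    return model


def save_ensemble(ensemble: EnsembleModel, out_dir: str | Path) -> Path:
    """Save members as npz archives plus a JSON fold map; returns the directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, member in enumerate(ensemble.members):
        arrays = {}
        for li, layer in enumerate(member.extractor.layers):
            for pi, p in enumerate(layer.params):
                arrays[f"layer{li}_p{pi}"] = p
        arrays["lda_means"] = member.lda.means
        arrays["lda_cov"] = member.lda.pooled_cov
        arrays["lda_priors"] = member.lda.priors
        arrays["selected"] = np.array(member.selection.selected_indices, dtype=np.int64)
        meta = {
            "extractor_config": dataclasses.asdict(member.extractor.config),
            "p_enter": member.selection.p_enter,
            "p_remove": member.selection.p_remove,
            "history": member.extractor.history.to_dict(orient="list"),
        }
        np.savez_compressed(out_dir / f"member{i:02d}.npz", **arrays)
        (out_dir / f"member{i:02d}.json").write_text(json.dumps(meta))
    (out_dir / "folds.json").write_text(
        json.dumps({"k": ensemble.k, "fold_of_case": ensemble.fold_of_case})
    )
    return out_dir


def load_ensemble(in_dir: str | Path) -> EnsembleModel:
    in_dir = Path(in_dir)
    folds = json.loads((in_dir / "folds.json").read_text())
    members = []
    for i in range(folds["k"]):
        meta = json.loads((in_dir / f"member{i:02d}.json").read_text())
        cfg_dict = meta["extractor_config"]
        for key in ("fc_sizes", "lr_decay_epochs"):
            cfg_dict[key] = tuple(cfg_dict[key])
        config = ExtractorConfig(**cfg_dict)
        data = np.load(in_dir / f"member{i:02d}.npz")
        layers = _build_network(config, np.random.default_rng(config.seed))
        for li, layer in enumerate(layers):
            for pi in range(len(layer.params)):
                layer.params[pi][...] = data[f"layer{li}_p{pi}"]
        extractor = TrainedExtractor(
            layers=layers, config=config, history=pd.DataFrame(meta["history"])
        )
        extractor.freeze()
        selected = tuple(int(j) for j in data["selected"])
        selection = SelectionResult(
            selected_indices=selected,
            trace=tuple((0, "enter", j, 0.0) for j in selected),
            p_enter=meta["p_enter"],
            p_remove=meta["p_remove"],
        )
        lda = LdaModel(means=data["lda_means"], pooled_cov=data["lda_cov"], priors=data["lda_priors"])
        members.append(MemberModel(extractor=extractor, selection=selection, lda=lda))
    return EnsembleModel(members=members, fold_of_case=folds["fold_of_case"], k=folds["k"])


# ---------------------------------------------------------------------------
# run configuration and orchestration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run.

    ``seed`` is the single source of randomness: the phantom, fold
    assignment and each member's extractor derive their streams from it.
    """

    phantom: PhantomConfig = field(default_factory=lambda: PhantomConfig(n_cases=120, train_size=60))
    extractor: ExtractorConfig = field(default_factory=lambda: ExtractorConfig.downsized())
    k_folds: int = 10
    p_enter: float = 0.05
    p_remove: float = 0.10
    n_boot: int = 2000
    seed: int = 0
    out_dir: str = "perceptcad_run"

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if not 0 < self.p_enter <= self.p_remove:
            raise ValueError("need 0 < p_enter <= p_remove")

    def to_dict(self) -> dict:
        return {
            "phantom": dataclasses.asdict(self.phantom),
            "extractor": dataclasses.asdict(self.extractor),
            "k_folds": self.k_folds,
            "p_enter": self.p_enter,
            "p_remove": self.p_remove,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        ph = data.pop("phantom", {})
        if "descriptor_marginals" in ph:
            ph["descriptor_marginals"] = {
                f: {float(k): v for k, v in m.items()}
                for f, m in ph["descriptor_marginals"].items()
            }
        for key in ("malignancy_logit_weights", "blur_sigmas", "contrast_levels",
                    "n_lobes_range", "n_spicules_range", "lesion_radius_frac"):
            if key in ph:
                ph[key] = tuple(ph[key])
        ex = data.pop("extractor", {})
        for key in ("fc_sizes", "lr_decay_epochs"):
            if key in ex:
                ex[key] = tuple(ex[key])
        return cls(phantom=PhantomConfig(**ph), extractor=ExtractorConfig(**ex), **data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run phantom generation, ensemble training, scoring and evaluation.

    Writes dataset, ensemble, ``scores.csv`` (case_id, per-view POMs, fused
    POM, label) and ``report.json`` (fused test AUC plus ROC points) under
    ``config.out_dir`` and returns the run summary, which is also written
    as ``run_summary.json``.  Deterministic given ``config.seed``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}, "artifacts": {}}
    config_json = json.dumps(config.to_dict(), sort_keys=True)
    summary["config_sha256"] = hashlib.sha256(config_json.encode()).hexdigest()[:16]

    def stage(name):
        logger.info("stage %s started", name)
        summary["stages"][name] = {"started": time.time()}

    def done(name):
        rec = summary["stages"][name]
        rec["seconds"] = round(time.time() - rec.pop("started"), 2)
        logger.info("stage %s finished in %.1fs", name, rec["seconds"])

    try:
        stage("synth")
        phantom_cfg = dataclasses.replace(config.phantom, seed=config.seed)
        if phantom_cfg.train_size is None:
            raise ValueError("run_pipeline needs phantom.train_size for the train/test split")
        cases, manifest = generate_dataset(phantom_cfg)
        manifest_path = write_dataset(cases, manifest, out_dir / "dataset")
        done("synth")

        stage("crossval")
        split = manifest.drop_duplicates("case_id").set_index("case_id")["split"]
        train_cases = [c for c in cases if split[c.case_id] == "train"]
        test_cases = [c for c in cases if split[c.case_id] == "test"]
        ensemble = crossval_train(
            train_cases,
            k=config.k_folds,
            extractor_config=config.extractor,
            p_enter=config.p_enter,
            p_remove=config.p_remove,
            seed=config.seed,
            progress=lambda msg: logger.info("%s", msg),
        )
        ensemble_dir = save_ensemble(ensemble, out_dir / "ensemble")
        done("crossval")

        stage("classify")
        rows = []
        for case in test_cases:
            score = fused_pom(ensemble, case)
            rows.append(
                {"case_id": case.case_id, "pom": score.pom, "label": case.label}
            )
        scores = pd.DataFrame(rows)
        scores_path = out_dir / "scores.csv"
        scores.to_csv(scores_path, index=False)
        done("classify")

        stage("evaluate")
        y = (scores["label"] == "malignant").astype(int).to_numpy()
        roc = roc_from_poms(scores["pom"].to_numpy(), y)
        report = {"n_test_cases": len(scores), "fused_auc": roc.auc}
        report_path = out_dir / "report.json"
        report_path.write_text(json.dumps(report, indent=2))
        roc_path = out_dir / "roc_points.csv"
        pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr}).to_csv(roc_path, index=False)
        done("evaluate")
    except Exception as exc:
        failed = [n for n, r in summary["stages"].items() if "seconds" not in r]
        raise RuntimeError(f"pipeline failed in stage {failed[-1] if failed else '?'}: {exc}") from exc

    summary["artifacts"] = {
        "manifest": {"path": str(manifest_path), "sha256": _sha256(manifest_path)},
        "ensemble": {"path": str(ensemble_dir)},
        "scores": {"path": str(scores_path), "sha256": _sha256(scores_path)},
        "report": {"path": str(report_path), "sha256": _sha256(report_path)},
    }
    summary["fused_auc"] = roc.auc
    (out_dir / "run_summary.json").write_text(json.dumps(summary, indent=2))
    return summary
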