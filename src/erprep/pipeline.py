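"""End-to-end study driver: simulate -> preprocess -> volumes -> fit -> group -> compare.

Two surfaces:

* :func:`analyze_dataset` — the in-memory pipeline used by tests and scripts:
  takes a simulation config, runs every stage, returns a :class:`StudyResult`.
* :func:`run_pipeline` — the on-disk, manifest-tracked version behind the CLI:
  each stage writes its outputs under the run directory, records their SHA-256
  hashes in ``manifest.json``, and is skipped on re-run when its config and
  outputs are unchanged.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import __version__
from .compare import (comparison_table, conjunction_mask, delta_lme,
                      summarize_comparison)
from .glm import LMEMap, build_design, compute_lme, fit_glm
from .group import GroupSample, RFTResult, SPMMap, group_inference
from .montage import Montage, make_default_montage
from .preprocess import AverageERPSet, PreprocConfig, preprocess
from .simulate import EffectSpec, EpochSet, SimulationConfig, inject_artifacts, simulate_subject
from .volume import (FrameInterpolator, ScalpGrid, SmoothingSpec,
                     project_electrodes, smooth_volumes)

MODEL_ORDER = ("exponential", "linear", "chdet")
PAIRS = (("exponential", "linear"), ("exponential", "chdet"), ("chdet", "linear"))


# ---------------------------------------------------------------------------
# in-memory pipeline
# ---------------------------------------------------------------------------

def subject_condition_matrix(
    avg: AverageERPSet,
    interp: FrameInterpolator,
    smoothing: SmoothingSpec = SmoothingSpec(),
    window_ms: tuple[float, float] = (50.0, 500.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smoothed scalp x time volumes of the 24 condition means, as a GLM matrix.

    Returns (Y, mask3d, frame_times): Y is (n_blocks*n_presentations, V) in
    block-major row order matching :func:`erprep.glm.build_design`.
    """
    n_scalp = avg.montage.n_scalp
    nb, npres = avg.counts.shape
    t = avg.times_ms
    lo, hi = window_ms
    if lo < t[0] - 1e-9 or hi > t[-1] + 1e-9:
        raise ValueError(f"analysis window {window_ms} outside epoch [{t[0]}, {t[-1]}] ms")
    sel = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    frame_times = t[sel]
    dt = float(frame_times[1] - frame_times[0])
    # block-major stacking of the condition means, matching build_design rows
    erps = avg.means[:, :, :n_scalp, :].reshape(nb * npres, n_scalp, t.size)
    frames = erps.transpose(0, 2, 1)[:, sel, :].reshape(-1, n_scalp)  # (24*T, ch)
    n = interp.grid.n_pixels
    raw = np.full((frames.shape[0], n * n), np.nan)
    raw[:, interp._flat_idx] = frames @ interp.weights.T
    values = raw.reshape(nb * npres, frame_times.size, n, n).transpose(0, 2, 3, 1)
    smoothed = smooth_volumes(values, interp.mask, interp.grid, dt, smoothing)
    mask3d = np.broadcast_to(interp.mask[:, :, None], smoothed.shape[1:]).copy()
    Y = smoothed[:, mask3d]
    return Y, mask3d, frame_times


@dataclass
class GroupResult:
    spm: SPMMap
    rft: RFTResult
    clusters: pd.DataFrame


@dataclass
class StudyResult:
    """Everything the analysis produces, in memory."""

    config: SimulationConfig
    grid: ScalpGrid
    montage: Montage
    mask3d: np.ndarray
    frame_times_ms: np.ndarray
    pooled: dict  # model -> (S, V) pooled modulator betas
    rss: dict  # model -> (S, V)
    lme: dict  # model -> list[LMEMap]
    group: dict  # model -> GroupResult
    deltas: dict  # (A, B) -> DeltaLMEMap
    summary: pd.DataFrame
    conjunction: np.ndarray  # flat (V,) mask, 'all' mode
    trial_counts: list
    n = property(lambda self: int(self.mask3d.sum()))

    def mask_volume(self, flat: np.ndarray) -> np.ndarray:
        out = np.full(self.mask3d.shape, np.nan)
        out[self.mask3d] = flat
        return out


def fit_subject_models(
    Y: np.ndarray,
    subject: int,
    models=MODEL_ORDER,
    tau: float = 1.0,
    n_blocks: int = 4,
    n_presentations: int = 6,
) -> dict:
    """Fit every rival design to one subject's condition matrix."""
    out = {}
    for model in models:
        design = build_design(model, n_blocks, n_presentations, tau)
        fit = fit_glm(Y, design, subject=subject)
        pooled = fit.betas[design.modulator_columns, :].mean(axis=0)
        out[model] = {"pooled": pooled, "rss": fit.rss, "lme": compute_lme(fit), "fit": fit}
    return out


def analyze_dataset(
    config: SimulationConfig,
    preproc: PreprocConfig = PreprocConfig(),
    grid: ScalpGrid = ScalpGrid(),
    smoothing: SmoothingSpec = SmoothingSpec(),
    window_ms: tuple[float, float] = (50.0, 500.0),
    models=MODEL_ORDER,
    tau: float = 1.0,
    alpha: float = 0.05,
    mask_mode: str = "all",
    artifact_fraction: float = 0.0,
    artifact_magnitude_uv: float = 120.0,
    montage: Montage | None = None,
) -> StudyResult:
    """Run the whole analysis on one synthetic dataset."""
    montage = montage or make_default_montage()
    interp = FrameInterpolator(project_electrodes(montage, grid), grid)

    pooled = {m: [] for m in models}
    rss = {m: [] for m in models}
    lmes = {m: [] for m in models}
    counts = []
    mask3d = frame_times = None
    for sid in range(config.n_subjects):
        epochs = simulate_subject(config, sid, montage=montage, grid=grid)
        if artifact_fraction > 0:
            epochs, _ = inject_artifacts(
                epochs, artifact_fraction, artifact_magnitude_uv, seed=config.seed + 7919 + sid
            )
        avg = preprocess(epochs, preproc)
        del epochs
        Y, mask3d, frame_times = subject_condition_matrix(avg, interp, smoothing, window_ms)
        counts.append(avg.counts.copy())
        fits = fit_subject_models(Y, sid, models, tau, config.n_blocks, config.n_presentations)
        for m in models:
            pooled[m].append(fits[m]["pooled"])
            rss[m].append(fits[m]["rss"])
            lmes[m].append(fits[m]["lme"])

    group = {}
    for m in models:
        sample = GroupSample(np.stack(pooled[m]), model=m)
        spm, rft, table = group_inference(
            sample, mask3d, frame_times, grid.pixel_size_mm, alpha
        )
        group[m] = GroupResult(spm=spm, rft=rft, clusters=table)

    sig_flat = [group[m].rft.significant_mask[mask3d] for m in models]
    conj = conjunction_mask(sig_flat, mode="all")
    mask_sets = {"within mask": conjunction_mask(sig_flat, mode=mask_mode),
                 "all voxels": np.ones(int(mask3d.sum()), dtype=bool)}

    deltas = {}
    rows = []
    for a, b in PAIRS:
        if a in lmes and b in lmes:
            d = delta_lme(lmes[a], lmes[b])
            deltas[(a, b)] = d
            for label, vset in mask_sets.items():
                if vset.any():
                    rows.append(summarize_comparison(d, vset, label=label))
    summary = comparison_table(rows)

    return StudyResult(
        config=config,
        grid=grid,
        montage=montage,
        mask3d=mask3d,
        frame_times_ms=frame_times,
        pooled={m: np.stack(pooled[m]) for m in models},
        rss={m: np.stack(rss[m]) for m in models},
        lme=lmes,
        group=group,
        deltas=deltas,
        summary=summary,
        conjunction=conj,
        trial_counts=counts,
    )


# ---------------------------------------------------------------------------
# configuration schema (strict: unknown keys are rejected)
# ---------------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EffectSection(_Strict):
    center_channel: str
    spatial_fwhm_mm: float = 50.0
    window_ms: tuple[float, float]
    sign: int = -1
    amplitude_uv: float = 2.0
    dynamics: str = "exponential"
    tau: float = 1.0


class SimulationSection(_Strict):
    n_subjects: int = 17
    n_blocks: int = 4
    n_objects_per_block: int = 60
    n_presentations: int = 6
    sampling_rate_hz: float = 500.0
    epoch_window_ms: tuple[float, float] = (-100.0, 550.0)
    soa_ms: float = 570.0
    noise_sd_uv: float = 2.0
    noise_spatial_lambda_mm: float = 65.0
    subject_sd_uv: float = 1.2
    artifact_fraction: float = 0.0
    artifact_magnitude_uv: float = 120.0
    effects: list[EffectSection] | None = None


class PreprocSection(_Strict):
    band_hz: tuple[float, float] = (1.0, 30.0)
    filter_order: int = 4
    baseline_window_ms: tuple[float, float] = (-100.0, 0.0)
    reject_threshold_uv: float = 75.0
    target_exclusion_ms: float = 800.0


class VolumeSection(_Strict):
    n_pixels: int = 32
    pixel_size_mm: float = 4.25
    head_radius_mm: float = 85.0
    fwhm: tuple[float, float, float] = (16.0, 16.0, 16.0)
    window_ms: tuple[float, float] = (50.0, 500.0)


class GLMSection(_Strict):
    models: tuple[str, ...] = MODEL_ORDER
    tau: float = 1.0


class GroupSection(_Strict):
    alpha: float = 0.05


class CompareSection(_Strict):
    mask_mode: str = "all"


class PipelineConfig(_Strict):
    """Validated, nested configuration of a full run."""

    seed: int = 0
    run_id: str = "run"
    simulation: SimulationSection = SimulationSection()
    preprocess: PreprocSection = PreprocSection()
    volume: VolumeSection = VolumeSection()
    glm: GLMSection = GLMSection()
    group: GroupSection = GroupSection()
    compare: CompareSection = CompareSection()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def sim_config(self) -> SimulationConfig:
        s = self.simulation
        kwargs = s.model_dump(exclude={"effects", "artifact_fraction", "artifact_magnitude_uv"})
        kwargs["epoch_window_ms"] = tuple(kwargs["epoch_window_ms"])
        if s.effects is not None:
            kwargs["effects"] = tuple(
                EffectSpec(
                    center_channel=e.center_channel,
                    spatial_fwhm_mm=e.spatial_fwhm_mm,
                    window_ms=tuple(e.window_ms),
                    sign=e.sign,
                    amplitude_uv=e.amplitude_uv,
                    dynamics=e.dynamics,
                    tau=e.tau,
                )
                for e in s.effects
            )
        return SimulationConfig(seed=self.seed, **kwargs)

    def preproc_config(self) -> PreprocConfig:
        p = self.preprocess
        return PreprocConfig(
            band_hz=tuple(p.band_hz),
            filter_order=p.filter_order,
            baseline_window_ms=tuple(p.baseline_window_ms),
            reject_threshold_uv=p.reject_threshold_uv,
            target_exclusion_ms=p.target_exclusion_ms,
        )

    def grid(self) -> ScalpGrid:
        v = self.volume
        return ScalpGrid(v.n_pixels, v.pixel_size_mm, v.head_radius_mm)

    def smoothing(self) -> SmoothingSpec:
        return SmoothingSpec(tuple(self.volume.fwhm))


# ---------------------------------------------------------------------------
# on-disk stages with a hash manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for block in iter(lambda: f.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _config_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()


class RunManifest:
    """Stage ledger of a run: per-stage config hash and output-file hashes."""

    def __init__(self, out_dir: Path, config: PipelineConfig):
        self.out_dir = Path(out_dir)
        self.path = self.out_dir / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
        else:
            self.data = {
                "run_id": config.run_id,
                "version": __version__,
                "config": config.model_dump(mode="json"),
                "stages": {},
            }

    def stage_current(self, name: str, cfg_hash: str) -> bool:
        st = self.data["stages"].get(name)
        if not st or st["config_hash"] != cfg_hash:
            return False
        return all(
            (self.out_dir / rel).exists() and _sha256(self.out_dir / rel) == digest
            for rel, digest in st["outputs"].items()
        )

    def record(self, name: str, cfg_hash: str, outputs: list[Path]) -> None:
        self.data["stages"][name] = {
            "config_hash": cfg_hash,
            "completed_at": datetime.now(timezone.utc).isoformat(),
            "outputs": {
                str(p.relative_to(self.out_dir)): _sha256(p) for p in outputs
            },
        }
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))

    def output_hashes(self) -> dict:
        return {
            rel: digest
            for st in self.data["stages"].values()
            for rel, digest in st["outputs"].items()
        }


_STAGE_ORDER = ("simulate", "preprocess", "fit", "group", "compare", "report")
_STAGE_ALIAS = {"volumes": "fit"}


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path, log=print, upto: str | None = None
) -> RunManifest:
    """Execute stages in order, skipping up-to-date ones; stop after ``upto``."""
    upto = _STAGE_ALIAS.get(upto, upto)
    if upto is not None and upto not in _STAGE_ORDER:
        raise ValueError(f"unknown stage {upto!r}")

    def done(stage: str) -> bool:
        return upto is not None and _STAGE_ORDER.index(stage) >= _STAGE_ORDER.index(upto)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(out, config)
    montage = make_default_montage()
    grid = config.grid()
    interp = FrameInterpolator(project_electrodes(montage, grid), grid)
    sim = config.sim_config()
    n_sub = sim.n_subjects

    # --- simulate ------------------------------------------------------
    cfgh = _config_hash({"sim": config.simulation.model_dump(mode="json"), "seed": config.seed})
    epoch_paths = [out / "epochs" / f"sub-{s:02d}_epochs.npy" for s in range(n_sub)]
    if manifest.stage_current("simulate", cfgh):
        log("simulate: up to date, skipped")
    else:
        outputs = []
        for sid in range(n_sub):
            ep = simulate_subject(sim, sid, montage=montage, grid=grid)
            if config.simulation.artifact_fraction > 0:
                ep, _ = inject_artifacts(
                    ep, config.simulation.artifact_fraction,
                    config.simulation.artifact_magnitude_uv, seed=config.seed + 7919 + sid,
                )
            p = ep.save(out / "epochs", stem=f"sub-{sid:02d}_epochs")
            outputs += [p, p.with_suffix(".json")]
            log(f"simulate: subject {sid} -> {p.name} ({ep.n_trials} trials)")
        manifest.record("simulate", cfgh, outputs)
    if done("simulate"):
        return manifest

    # --- preprocess ------------------------------------------------------
    cfgh = _config_hash(
        {"pre": config.preprocess.model_dump(mode="json"),
         "upstream": manifest.data["stages"]["simulate"]["config_hash"]}
    )
    erp_dir = out / "erps"
    if manifest.stage_current("preprocess", cfgh):
        log("preprocess: up to date, skipped")
    else:
        erp_dir.mkdir(parents=True, exist_ok=True)
        outputs = []
        for sid, ep_path in enumerate(epoch_paths):
            epochs = EpochSet.load(ep_path)
            avg = preprocess(epochs, config.preproc_config())
            del epochs
            p = erp_dir / f"sub-{sid:02d}_erps.npy"
            np.save(p, avg.means.astype("<f4"))
            meta = {
                "counts": avg.counts.tolist(),
                "times_ms": avg.times_ms.tolist(),
                "subject": avg.subject,
                "n_rejected": avg.meta.get("n_rejected", 0),
                "preproc": avg.meta.get("preproc", {}),
            }
            (erp_dir / f"sub-{sid:02d}_erps.json").write_text(json.dumps(meta, sort_keys=True))
            outputs += [p, erp_dir / f"sub-{sid:02d}_erps.json"]
            log(f"preprocess: subject {sid} ({meta['n_rejected']} trials rejected)")
        manifest.record("preprocess", cfgh, outputs)
    if done("preprocess"):
        return manifest

    def load_erps(sid) -> AverageERPSet:
        meta = json.loads((erp_dir / f"sub-{sid:02d}_erps.json").read_text())
        return AverageERPSet(
            means=np.load(erp_dir / f"sub-{sid:02d}_erps.npy").astype(float),
            counts=np.array(meta["counts"], dtype=int),
            times_ms=np.array(meta["times_ms"]),
            montage=montage,
            subject=meta["subject"],
            meta=meta,
        )

    # --- volumes + fit (per subject) ------------------------------------
    cfgh = _config_hash(
        {
            "vol": config.volume.model_dump(mode="json"),
            "glm": config.glm.model_dump(mode="json"),
            "upstream": manifest.data["stages"]["preprocess"]["config_hash"],
        }
    )
    if manifest.stage_current("fit", cfgh):
        log("fit: up to date, skipped")
    else:
        outputs = []
        fit_dir = out / "fit"
        fit_dir.mkdir(parents=True, exist_ok=True)
        for sid in range(n_sub):
            avg = load_erps(sid)
            Y, mask3d, frame_times = subject_condition_matrix(
                avg, interp, config.smoothing(), tuple(config.volume.window_ms)
            )
            fits = fit_subject_models(
                Y, sid, config.glm.models, config.glm.tau, sim.n_blocks, sim.n_presentations
            )
            for m in config.glm.models:
                p = fit_dir / f"sub-{sid:02d}_{m}.npy"
                np.save(p, np.stack([fits[m]["pooled"], fits[m]["rss"], fits[m]["lme"].lme]))
                outputs.append(p)
            log(f"fit: subject {sid} ({int(mask3d.sum())} voxels)")
        np.save(out / "fit" / "mask3d.npy", mask3d)
        np.save(out / "fit" / "frame_times_ms.npy", frame_times)
        outputs += [out / "fit" / "mask3d.npy", out / "fit" / "frame_times_ms.npy"]
        manifest.record("fit", cfgh, outputs)
    if done("fit"):
        return manifest

    mask3d = np.load(out / "fit" / "mask3d.npy")
    frame_times = np.load(out / "fit" / "frame_times_ms.npy")

    def load_fit(sid, m):
        arr = np.load(out / "fit" / f"sub-{sid:02d}_{m}.npy")
        return arr[0], arr[1], arr[2]  # pooled, rss, lme

    # --- group ----------------------------------------------------------
    cfgh = _config_hash(
        {"group": config.group.model_dump(mode="json"),
         "upstream": manifest.data["stages"]["fit"]["config_hash"]}
    )
    group_dir = out / "group"
    if manifest.stage_current("group", cfgh):
        log("group: up to date, skipped")
    else:
        group_dir.mkdir(parents=True, exist_ok=True)
        outputs = []
        for m in config.glm.models:
            pooled = np.stack([load_fit(s, m)[0] for s in range(n_sub)])
            spm, rft, table = group_inference(
                GroupSample(pooled, m), mask3d, frame_times,
                grid.pixel_size_mm, config.group.alpha,
            )
            np.save(group_dir / f"{m}_F.npy", spm.F)
            np.save(group_dir / f"{m}_sigmask.npy", rft.significant_mask)
            table.to_csv(group_dir / f"{m}_clusters.csv", index=False)
            (group_dir / f"{m}_rft.json").write_text(json.dumps(
                {
                    "fwhm_est_voxels": rft.fwhm_est.tolist(),
                    "resel_counts": rft.resel_counts.tolist(),
                    "search_volume_voxels": rft.search_volume,
                    "alpha": rft.alpha,
                    "f_threshold": rft.f_threshold,
                    "df": list(spm.df),
                    "n_significant_voxels": int(rft.significant_mask.sum()),
                }, indent=1, sort_keys=True))
            outputs += [group_dir / f"{m}_{sfx}" for sfx in
                        ("F.npy", "sigmask.npy", "clusters.csv", "rft.json")]
            log(f"group[{m}]: F threshold {rft.f_threshold:.2f}, "
                f"{int(rft.significant_mask.sum())} significant voxels, "
                f"{table['activation'].nunique() if len(table) else 0} clusters")
        manifest.record("group", cfgh, outputs)
    if done("group"):
        return manifest

    # --- compare ---------------------------------------------------------
    cfgh = _config_hash(
        {"compare": config.compare.model_dump(mode="json"),
         "upstream": manifest.data["stages"]["group"]["config_hash"]}
    )
    comp_dir = out / "compare"
    if manifest.stage_current("compare", cfgh):
        log("compare: up to date, skipped")
    else:
        comp_dir.mkdir(parents=True, exist_ok=True)
        lmes = {
            m: [LMEMap(lme=load_fit(s, m)[2], model=m, subject=s) for s in range(n_sub)]
            for m in config.glm.models
        }
        sig_flat = [
            np.load(group_dir / f"{m}_sigmask.npy")[mask3d] for m in config.glm.models
        ]
        mask_sets = {
            "within mask": conjunction_mask(sig_flat, mode=config.compare.mask_mode),
            "all voxels": np.ones(int(mask3d.sum()), dtype=bool),
        }
        rows, outputs = [], []
        for a, b in PAIRS:
            if a in lmes and b in lmes:
                d = delta_lme(lmes[a], lmes[b])
                np.save(comp_dir / f"delta_{a}_vs_{b}.npy", d.group_sum)
                outputs.append(comp_dir / f"delta_{a}_vs_{b}.npy")
                for label, vset in mask_sets.items():
                    if vset.any():
                        rows.append(summarize_comparison(d, vset, label=label))
        comparison_table(rows).to_csv(comp_dir / "comparison.csv", index=False)
        outputs.append(comp_dir / "comparison.csv")
        manifest.record("compare", cfgh, outputs)
        log(f"compare: wrote {comp_dir / 'comparison.csv'}")
    if done("compare"):
        return manifest

    # --- report ----------------------------------------------------------
    cfgh = _config_hash({"upstream": manifest.data["stages"]["compare"]["config_hash"]})
    if manifest.stage_current("report", cfgh):
        log("report: up to date, skipped")
    else:
        outputs = write_report(config, out, mask3d, frame_times, grid, montage)
        manifest.record("report", cfgh, outputs)
        log(f"report: wrote {len(outputs)} files under {out / 'report'}")
    return manifest


def write_report(
    config: PipelineConfig,
    out: Path,
    mask3d: np.ndarray,
    frame_times: np.ndarray,
    grid: ScalpGrid,
    montage: Montage,
) -> list[Path]:
    """Cluster table, comparison table, peak scalp maps, per-electrode box data."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rep = out / "report"
    rep.mkdir(parents=True, exist_ok=True)
    outputs = []
    report_cols = ["activation", "size", "latency_ms", "p_fwe", "F", "Z"]
    for m in config.glm.models:
        src = out / "group" / f"{m}_clusters.csv"
        if not src.exists():
            raise FileNotFoundError(f"missing group output for model {m!r}; run the group stage")
        table = pd.read_csv(src)
        dst = rep / f"clusters_{m}.csv"
        if len(table) == 0:
            dst.write_text(",".join(report_cols) + "\n")
            (rep / f"clusters_{m}.txt").write_text("no suprathreshold voxels\n")
            outputs.append(rep / f"clusters_{m}.txt")
        else:
            table[report_cols].to_csv(dst, index=False)
        outputs.append(dst)

    # scalp maps of the winning-model F statistic at each cluster peak latency
    best = config.glm.models[0]
    F = np.load(out / "group" / f"{best}_F.npy")
    F_vol = np.full(mask3d.shape, np.nan)
    F_vol[mask3d] = F
    table = pd.read_csv(out / "group" / f"{best}_clusters.csv")
    peak_latencies = sorted(set(table["latency_ms"])) if len(table) else []
    for lat in peak_latencies[:6]:
        fi = int(np.argmin(np.abs(frame_times - lat)))
        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(F_vol[:, :, fi].T, origin="lower", cmap="viridis")
        ax.set_title(f"{best} F map at {frame_times[fi]:.0f} ms")
        fig.colorbar(im, ax=ax, label="F")
        p = rep / f"scalp_F_{best}_{int(round(frame_times[fi]))}ms.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        outputs.append(p)

    comp = out / "compare" / "comparison.csv"
    if comp.exists():
        dst = rep / "comparison.csv"
        dst.write_bytes(comp.read_bytes())
        outputs.append(dst)

    # per-electrode ERP amplitude by presentation (box-plot data): for each
    # activation of the winning model, the electrode nearest the peak pixel,
    # mean amplitude in peak latency +/- 8 ms, pooled over blocks, per subject
    if len(table) and (out / "erps").exists():
        xy = project_electrodes(montage, grid)
        centers = grid.pixel_centers_mm
        rows = []
        first_peaks = table.groupby("activation").first().reset_index()
        for _, r in first_peaks.iterrows():
            px = np.array([centers[int(r["peak_ix"])], centers[int(r["peak_iy"])]])
            elec = int(np.argmin(((xy - px) ** 2).sum(axis=1)))
            sid = 0
            while (out / "erps" / f"sub-{sid:02d}_erps.npy").exists():
                means = np.load(out / "erps" / f"sub-{sid:02d}_erps.npy")
                meta = json.loads((out / "erps" / f"sub-{sid:02d}_erps.json").read_text())
                t = np.array(meta["times_ms"])
                win = (t >= r["latency_ms"] - 8.0) & (t <= r["latency_ms"] + 8.0)
                amp = means[:, :, elec, win].mean(axis=(0, 2))  # pooled over blocks
                for pres, a in enumerate(amp, start=1):
                    rows.append(
                        {
                            "activation": int(r["activation"]),
                            "electrode": montage.labels[elec],
                            "latency_ms": float(r["latency_ms"]),
                            "subject": sid,
                            "presentation": pres,
                            "amplitude_uv": float(a),
                        }
                    )
                sid += 1
        box = rep / "boxplot_data.csv"
        pd.DataFrame(rows).to_csv(box, index=False)
        outputs.append(box)
    return outputs
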