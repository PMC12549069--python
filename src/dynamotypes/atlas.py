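"""End-to-end seizure generation, the dynamotype atlas, and database sweeps.

``generate_seizure`` runs the full pipeline for one class-method pair:
build the path from its validated recipe, assign the dynamical-noise
amplitude (from the class's calibrated noise surface), integrate, label
events, and post-process into an EEG-like record with full provenance.

``generate_atlas`` produces the sample atlas: for every class-method pair,
several paths spread along the legal anchor spans, each simulated at three
noise levels (none / low / high).  ``generate_database`` sweeps onset and
offset anchor fractions independently for the hysteresis and slow-wave
classes, with per-record noise amplitudes interpolated from the fitted
surfaces, and writes records plus an append-only checksummed manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .calibration import NoiseSurface, lookup_sigma
from .integrate import IntegratorConfig, integrate
from .paths import BurstingPath
from .postprocess import SeizureRecord, polarity_double, postprocess
from .registry import DynamotypeSpec, PathRecipe, get_recipe, get_spec, recipes, registry
from .sphere import CurveSet, load_packaged_curves

__all__ = [
    "AtlasConfig",
    "NOISE_LEVELS",
    "generate_seizure",
    "generate_atlas",
    "generate_database",
    "load_noise_surface",
    "recommended_duration",
]

logger = logging.getLogger(__name__)

#: atlas noise levels: (dynamical-noise multiple of the calibrated
#: sigma_star, background-noise alpha).  "low" pairs the calibrated
#: amplitude with moderate background noise; "high" uses four times the
#: calibrated amplitude with high background noise.
NOISE_LEVELS: dict[str, tuple[float, float]] = {
    "none": (0.0, 0.0),
    "low": (1.0, 0.20),
    "high": (4.0, 0.40),
}

_DATA_DIR = Path(__file__).parent / "data"


def load_noise_surface(onset: str, offset: str, method: str) -> NoiseSurface | None:
    """Packaged calibrated noise surface for a class-method pair, or None
    when no surface has been calibrated for it."""
    stem = _DATA_DIR / f"noise_{onset}_{offset}_{method}".replace("/", "_")
    if not stem.with_suffix(".csv").exists():
        return None
    return NoiseSurface.load(stem)


def load_default_sigma(onset: str, offset: str, method: str) -> float:
    """Packaged calibrated noise amplitude for a class-method pair's
    canonical path (used when no surface exists, e.g. for the single-anchor
    fold/circle recipe); zero when nothing was calibrated."""
    path = _DATA_DIR / "calibration_defaults.json"
    if not path.exists():
        return 0.0
    table = json.loads(path.read_text())
    entry = table.get(f"{onset}/{offset}/{method}")
    return float(entry["sigma"]) if entry else 0.0


def recommended_duration(path: BurstingPath, recipe: PathRecipe) -> float:
    """Simulation length (model time) covering approach, seizure and
    post-seizure margin for a recipe's path."""
    if path.kind == "hysteresis":
        return recipe.duration
    if path.kind == "slow_wave":
        return (path.z_offset - path.z_start) / abs(path.config.k) + 3000.0
    return path.total_traversal_time + 1000.0


@dataclass
class AtlasConfig:
    """Atlas generation settings: how many paths per class-method pair,
    which noise levels, the base seed, and where records are written."""

    paths_per_class: int = 5
    noise_levels: tuple[str, ...] = ("none", "low", "high")
    base_seed: int = 0
    outdir: Path = Path("atlas")
    tstep: float = 0.05
    polarity_doubling: bool = False

    def __post_init__(self) -> None:
        if self.paths_per_class < 1:
            raise ValueError("paths_per_class must be at least 1")
        order = list(NOISE_LEVELS)
        if list(self.noise_levels) != sorted(
            self.noise_levels, key=order.index
        ):
            raise ValueError("noise levels must be ordered none < low < high")
        self.outdir = Path(self.outdir)


def generate_seizure(
    spec: DynamotypeSpec | tuple[str, str],
    method: str | None = None,
    u: float = 0.5,
    u_onset: float | None = None,
    u_offset: float | None = None,
    noise_level: str = "none",
    seed: int = 0,
    sigma: float | None = None,
    alpha: float | None = None,
    cutoff: float | None = None,
    target_rate: float = 10.0,
    curves: CurveSet | None = None,
    tstep: float = 0.05,
    duration: float | None = None,
) -> SeizureRecord:
    """Generate one fully post-processed, labelled seizure.

    ``noise_level`` maps to (dynamical sigma, background alpha) via
    :data:`NOISE_LEVELS`; explicit ``sigma``/``alpha`` override it.  The
    dynamical-noise amplitude at "low" is the class's calibrated
    ``sigma_star`` (surface lookup, falling back to the recipe default);
    "high" is four times that.  The record carries full provenance: class,
    method, anchors, sweep coordinates, noise and filter settings, seed.
    """
    if isinstance(spec, tuple):
        spec = get_spec(*spec)
    method = method or spec.methods[0]
    recipe = get_recipe(spec.onset, spec.offset, method)
    curves = curves or load_packaged_curves()
    path = recipe.build(curves, u=u, u_onset=u_onset, u_offset=u_offset)

    if noise_level not in NOISE_LEVELS:
        raise ValueError(f"unknown noise level {noise_level!r}")
    sigma_mult, level_alpha = NOISE_LEVELS[noise_level]
    if sigma is None:
        if sigma_mult == 0.0:
            sigma = 0.0
        else:
            surface = load_noise_surface(spec.onset, spec.offset, method)
            if surface is not None:
                sigma = sigma_mult * lookup_sigma(surface, path)
            else:
                sigma = sigma_mult * (
                    load_default_sigma(spec.onset, spec.offset, method)
                    or recipe.default_sigma
                )
    if alpha is None:
        alpha = level_alpha

    config = IntegratorConfig(
        tstep=tstep,
        duration=duration or recommended_duration(path, recipe),
        seed=seed,
        sigma=sigma,
    )
    result = integrate(path, config=config)
    if not result.has_labels:
        raise RuntimeError(
            f"integration stage produced no labelled seizure for {spec.name} "
            f"[{method}] (seed {seed}, sigma {sigma:.3g})"
        )
    labels = {
        "onset": spec.onset,
        "offset": spec.offset,
        "dynamotype": spec.name,
        "method": method,
        "dc_onset_expected": spec.dc_onset,
        "dc_offset_expected": spec.dc_offset,
        **path.metadata,
    }
    try:
        record = postprocess(
            result,
            alpha=alpha,
            cutoff=cutoff,
            target_rate=target_rate,
            labels=labels,
            seed=seed,
        )
    except ValueError as exc:
        raise RuntimeError(
            f"post-processing stage failed for {spec.name} [{method}]: {exc}"
        ) from exc
    record.provenance["integrator"] = config.to_dict()
    return record


def _record_row(name: str, rec: SeizureRecord) -> dict:
    digest = hashlib.sha256(np.ascontiguousarray(rec.trace).tobytes()).hexdigest()[:16]
    return {
        "record": name,
        "dynamotype": rec.labels.get("dynamotype", ""),
        "method": rec.labels.get("method", ""),
        "sweep_u_onset": rec.labels.get("sweep_u_onset", ""),
        "sweep_u_offset": rec.labels.get("sweep_u_offset", ""),
        "noise_alpha": rec.noise_alpha,
        "sigma": rec.provenance.get("integrator", {}).get("sigma", ""),
        "seed": rec.seed,
        "fs_hz": rec.fs,
        "onset_sample": rec.onset_sample,
        "offset_sample": rec.offset_sample,
        "polarity": rec.polarity,
        "sha256_16": digest,
    }


def _write_manifest(rows: list[dict], outdir: Path, name: str) -> Path:
    import csv

    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / name
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    return path


def generate_atlas(
    config: AtlasConfig | None = None,
    curves: CurveSet | None = None,
    classes: list[tuple[str, str, str]] | None = None,
) -> dict:
    """Generate the sample atlas and return its manifest.

    For every class-method pair (all 17 by default): ``paths_per_class``
    anchor positions equally spaced along the legal sweep span, each
    simulated at every configured noise level.  Failed records are logged
    and reported as gaps in the manifest, never silently dropped.
    """
    config = config or AtlasConfig()
    curves = curves or load_packaged_curves()
    keys = classes or sorted(recipes().keys())
    rows: list[dict] = []
    gaps: list[dict] = []
    config.outdir.mkdir(parents=True, exist_ok=True)
    if config.paths_per_class == 1:
        us = [0.5]
    else:
        us = list(np.linspace(0.0, 1.0, config.paths_per_class))
    for onset, offset, method in keys:
        spec = get_spec(onset, offset)
        for pi, u in enumerate(us):
            for level in config.noise_levels:
                name = f"{onset}_{offset}_{method}_p{pi}_{level}"
                seed = config.base_seed + len(rows) + len(gaps)
                try:
                    rec = generate_seizure(
                        spec, method=method, u=float(u),
                        noise_level=level, seed=seed,
                        curves=curves, tstep=config.tstep,
                    )
                except Exception as exc:  # gap, reported in manifest
                    logger.warning("atlas record %s failed: %s", name, exc)
                    gaps.append({"record": name, "error": str(exc)})
                    continue
                recs = polarity_double([rec]) if config.polarity_doubling else [rec]
                for kk, r in enumerate(recs):
                    rname = name if kk == 0 else f"{name}_flip"
                    r.save_csv(config.outdir / rname)
                    rows.append(_record_row(rname, r))
    manifest = {
        "n_records": len(rows),
        "n_gaps": len(gaps),
        "gaps": gaps,
        "config": {
            "paths_per_class": config.paths_per_class,
            "noise_levels": list(config.noise_levels),
            "base_seed": config.base_seed,
            "tstep": config.tstep,
        },
    }
    if rows:
        path = _write_manifest(rows, config.outdir, "atlas_manifest.csv")
        manifest["manifest_csv"] = str(path)
        manifest["checksum"] = hashlib.sha256(
            "".join(r["sha256_16"] for r in rows).encode()
        ).hexdigest()[:16]
    (config.outdir / "atlas_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


@dataclass
class DatabaseConfig:
    """Database sweep settings: anchor-fraction grids for the swept classes,
    with the key model parameters (alpha, k, k_fast, d_star) held constant."""

    n_onset: int = 4
    n_offset: int = 4
    methods: tuple[str, ...] = ("hysteresis", "slow_wave")
    alpha: float = 0.20
    base_seed: int = 0
    outdir: Path = Path("database")
    tstep: float = 0.05
    polarity_doubling: bool = True

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)


def generate_database(
    config: DatabaseConfig | None = None,
    curves: CurveSet | None = None,
) -> dict:
    """Sweep onset x offset anchor fractions for the hysteresis and
    slow-wave classes and write the records plus manifest.

    Per-record dynamical noise comes from each class's fitted noise
    surface; classes without a surface are skipped with a warning.  The
    single-curve fold/circle recipe has one anchor, so only its onset
    fraction is swept.  Polarity doubling (amplitude flip) doubles the
    record count when enabled.
    """
    config = config or DatabaseConfig()
    curves = curves or load_packaged_curves()
    rows: list[dict] = []
    skipped: list[str] = []
    config.outdir.mkdir(parents=True, exist_ok=True)
    for (onset, offset, method), recipe in sorted(recipes().items()):
        if method not in config.methods:
            continue
        surface = load_noise_surface(onset, offset, method)
        if surface is None:
            logger.warning(
                "no calibrated noise surface for %s/%s [%s]; skipped",
                onset, offset, method,
            )
            skipped.append(f"{onset}/{offset} [{method}]")
            continue
        spec = get_spec(onset, offset)
        u_ons = np.linspace(0.0, 1.0, config.n_onset)
        u_offs = (
            [None] if recipe.offset_anchor is None
            else np.linspace(0.0, 1.0, config.n_offset)
        )
        for i, u_on in enumerate(u_ons):
            for j, u_off in enumerate(u_offs):
                name = f"{onset}_{offset}_{method}_{i}_{j}"
                seed = config.base_seed + len(rows)
                path = recipe.build(
                    curves, u_onset=float(u_on),
                    u_offset=None if u_off is None else float(u_off),
                )
                sigma = lookup_sigma(surface, path)
                try:
                    rec = generate_seizure(
                        spec, method=method,
                        u_onset=float(u_on),
                        u_offset=None if u_off is None else float(u_off),
                        noise_level="low", sigma=sigma, alpha=config.alpha,
                        seed=seed, curves=curves, tstep=config.tstep,
                    )
                except Exception as exc:
                    logger.warning("database record %s failed: %s", name, exc)
                    continue
                recs = [rec]
                if config.polarity_doubling:
                    recs = polarity_double(recs)
                for kk, r in enumerate(recs):
                    rname = name if kk == 0 else f"{name}_flip"
                    r.save_csv(config.outdir / rname)
                    rows.append(_record_row(rname, r))
    manifest = {
        "n_records": len(rows),
        "skipped_classes": skipped,
        "config": {
            "n_onset": config.n_onset,
            "n_offset": config.n_offset,
            "methods": list(config.methods),
            "alpha": config.alpha,
            "base_seed": config.base_seed,
            "polarity_doubling": config.polarity_doubling,
        },
    }
    if rows:
        path = _write_manifest(rows, config.outdir, "database_manifest.csv")
        manifest["manifest_csv"] = str(path)
    (config.outdir / "database_manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
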