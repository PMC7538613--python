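"""End-to-end orchestration: phantom cohort → scoring → volumetry → report.

The pipeline instantiates a synthetic cohort with a planted score-lesion
association, renders one angiography phantom and one lesion phantom per
animal, runs the patency scoring and edema-corrected volumetry on the
rendered images, correlates the recovered quantities, and finishes with the
ANOVA/ANCOVA power curve.  Every CSV artifact carries provenance header
lines (package version, config hash, seed); all randomness derives from the
single config seed, so a rerun reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._io import save_nifti, write_csv
from .angio import (
    RAYLEIGH_SD_FACTOR,
    SliceSlab,
    estimate_noise,
    pcoma_score,
    snr_map,
    threshold_map,
)
from .lesion import edema_corrected_lesion_percent
from .phantom import (
    CohortConfig,
    make_angiophantom,
    make_cohort,
    make_lesion_phantom,
    pcoma_corridor,
    pcoma_slab,
    willis_phantom_config,
)
from .powersim import PAPER_R2_GRID, TrialConfig, power_grid
from .stats import pearson, spearman

__all__ = ["RunConfig", "validate_config", "run_pipeline"]

log = logging.getLogger("pcoma")

_DEFAULT_SLAB = pcoma_slab()

# key -> (default, caster, validator or None)
_SCHEMA: dict[str, tuple[Any, Any, Any]] = {
    "seed": (0, int, None),
    "out_dir": ("pcoma_run", str, None),
    "n_animals": (8, int, lambda v: v >= 3 or "n_animals must be >= 3"),
    "target_r2": (0.34, float, lambda v: 0.0 <= v <= 1.0 or "target_r2 must be in [0, 1]"),
    "slope_sign": ("negative", str, lambda v: v in ("negative", "positive") or "slope_sign must be 'negative' or 'positive'"),
    "score_mean": (8.0, float, lambda v: v > 0 or "score_mean must be > 0"),
    "score_sd": (4.0, float, lambda v: v > 0 or "score_sd must be > 0"),
    "lesion_mean": (20.0, float, lambda v: 0 <= v <= 100 or "lesion_mean must be in [0, 100]"),
    "lesion_sd": (8.0, float, lambda v: v >= 0 or "lesion_sd must be >= 0"),
    "noise_sigma": (2.0, float, lambda v: v > 0 or "noise_sigma must be > 0"),
    "threshold_fraction": (0.1, float, lambda v: 0.0 < v <= 1.0 or "threshold_fraction must be in (0, 1]"),
    "noise_correction": (RAYLEIGH_SD_FACTOR, float, lambda v: v > 0 or "noise_correction must be > 0"),
    "slab_first": (_DEFAULT_SLAB.first_slice, int, lambda v: v >= 0 or "slab_first must be >= 0"),
    "slab_last": (_DEFAULT_SLAB.last_slice, int, lambda v: v >= 0 or "slab_last must be >= 0"),
    "side": ("left", str, lambda v: v in ("left", "right") or "side must be 'left' or 'right'"),
    "alpha": (0.05, float, lambda v: 0.0 < v < 1.0 or "alpha must be in (0, 1)"),
    "reps": (1000, int, lambda v: v >= 100 or "reps must be >= 100"),
    "d": (1.0, float, lambda v: v >= 0 or "d must be >= 0"),
    "n_per_group": (14, int, lambda v: v >= 2 or "n_per_group must be >= 2"),
    "sides": (2, int, lambda v: v in (1, 2) or "sides must be 1 or 2"),
    "r2_grid": ("paper", None, None),
}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated, fully defaulted pipeline configuration."""

    values: dict[str, Any]

    def __getattr__(self, key: str) -> Any:
        try:
            return self.values[key]
        except KeyError as exc:  # pragma: no cover - attribute protocol
            raise AttributeError(key) from exc

    @property
    def slab(self) -> SliceSlab:
        return SliceSlab(self.values["slab_first"], self.values["slab_last"])

    @property
    def grid(self) -> tuple[float, ...]:
        g = self.values["r2_grid"]
        return tuple(PAPER_R2_GRID) if g == "paper" else tuple(float(v) for v in g)

    def sha256(self) -> str:
        payload = json.dumps(self.values, sort_keys=True, default=str).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def validate_config(raw: str | Mapping[str, Any] | None) -> RunConfig:
    """Parse and validate a key-value config document (YAML text or mapping).

    Missing keys receive their documented defaults (threshold fraction 1/10,
    slab length 10, Rayleigh correction 0.6551, alpha 0.05, 1000 reps);
    unknown keys and out-of-range values are rejected by name.
    """
    if raw is None:
        data: dict[str, Any] = {}
    elif isinstance(raw, str):
        parsed = yaml.safe_load(raw)
        if parsed is None:
            parsed = {}
        if not isinstance(parsed, dict):
            raise ValueError("config must be a key-value document")
        data = parsed
    else:
        data = dict(raw)

    unknown = set(data) - set(_SCHEMA)
    if unknown:
        raise ValueError(f"unknown config key: {sorted(unknown)[0]!r}")

    values: dict[str, Any] = {}
    for key, (default, caster, validator) in _SCHEMA.items():
        value = data.get(key, default)
        if caster is not None:
            try:
                value = caster(value)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"config key {key!r}: cannot interpret {value!r}") from exc
        if validator is not None:
            ok = validator(value)
            if ok is not True:
                raise ValueError(f"config key {key!r}: {ok}")
        values[key] = value
    if values["slab_last"] < values["slab_first"]:
        raise ValueError("config key 'slab_last': must be >= slab_first")
    if values["r2_grid"] != "paper":
        grid = values["r2_grid"]
        if not isinstance(grid, (list, tuple)) or not all(
            isinstance(v, (int, float)) and 0.0 <= float(v) < 1.0 for v in grid
        ):
            raise ValueError("config key 'r2_grid': must be 'paper' or a list of values in [0, 1)")
        values["r2_grid"] = [float(v) for v in grid]
    return RunConfig(values=values)


def _child_seed(master: int, *key: int) -> int:
    return int(np.random.SeedSequence([int(master), *key]).generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict[str, Path]:
    """Run phantom → score → lesion → cohort report → power simulation.

    Returns the paths of the five artifacts: ``scores`` (per-animal patency
    CSV), ``lesions`` (per-animal volumetry CSV), ``cohort`` (merged table),
    ``correlations`` (score-vs-lesion report) and ``power_curve``.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    provenance = [
        f"pcoma v{__version__}",
        f"config_sha256: {config.sha256()}",
        f"seed: {config.seed}",
    ]
    artifacts: dict[str, Path] = {}
    try:
        t0 = time.perf_counter()
        log.info("stage 1/5: synthetic cohort (n=%d, planted r2=%.3g)", config.n_animals, config.target_r2)
        cohort_truth = make_cohort(
            CohortConfig(
                n_animals=config.n_animals,
                target_r2=config.target_r2,
                slope_sign=config.slope_sign,
                score_mean=config.score_mean,
                score_sd=config.score_sd,
                lesion_mean=config.lesion_mean,
                lesion_sd=config.lesion_sd,
                seed=_child_seed(config.seed, 1),
            )
        )
        write_csv(out / "ground_truth.csv", cohort_truth, provenance)

        log.info("stage 2/5: phantom rendering and patency scoring")
        phantom_dir = out / "phantoms"
        phantom_dir.mkdir(exist_ok=True)
        corridor = pcoma_corridor(side=config.side)
        slab = config.slab
        score_rows, lesion_rows = [], []
        for i, row in cohort_truth.iterrows():
            planted_snr = max(float(row["score"]), 0.0)
            pconf = willis_phantom_config(
                seed=_child_seed(config.seed, 2, i),
                noise_sigma=config.noise_sigma,
                pcoma_snr=(planted_snr, planted_snr),
            )
            volume, _truth = make_angiophantom(pconf)
            save_nifti(phantom_dir / f"{row['animal_id']}_tof.nii.gz", volume.intensities, volume.voxel_size)
            sigma = estimate_noise(volume, correction=config.noise_correction)
            thresholded = threshold_map(snr_map(volume, sigma), config.threshold_fraction)
            result = pcoma_score(thresholded, corridor, slab)
            score_rows.append(
                {
                    "animal_id": row["animal_id"],
                    "side": config.side,
                    "sigma": sigma,
                    "cutoff": result.cutoff,
                    "score": result.score,
                    "no_signal": result.no_signal,
                }
            )

            lesion_mask, ipsi, _contra = make_lesion_phantom(
                volume.shape,
                lesion_fraction=float(row["lesion_percent"]) / 100.0,
                seed=_child_seed(config.seed, 3, i),
            )
            save_nifti(phantom_dir / f"{row['animal_id']}_lesion.nii.gz", lesion_mask, volume.voxel_size)
            lesion_rows.append(
                {
                    "animal_id": row["animal_id"],
                    "lesion_voxels": int(lesion_mask.sum()),
                    "hemisphere_voxels": int(ipsi.sum()),
                    "lesion_percent": edema_corrected_lesion_percent(lesion_mask, ipsi),
                }
            )

        scores = pd.DataFrame(score_rows)
        artifacts["scores"] = write_csv(out / "scores.csv", scores, provenance)
        log.info("stage 3/5: lesion volumetry")
        lesions = pd.DataFrame(lesion_rows)
        artifacts["lesions"] = write_csv(out / "lesions.csv", lesions, provenance)

        log.info("stage 4/5: cohort merge and correlation report")
        cohort = scores.merge(lesions, on="animal_id")
        artifacts["cohort"] = write_csv(out / "cohort.csv", cohort, provenance)
        pe = pearson(cohort["score"], cohort["lesion_percent"])
        sp = spearman(cohort["score"], cohort["lesion_percent"])
        report = pd.DataFrame(
            [
                {"method": r.method, "r": r.r, "r2": r.r2, "p": r.p, "n": r.n}
                for r in (pe, sp)
            ]
        )
        artifacts["correlations"] = write_csv(out / "correlations.csv", report, provenance)

        log.info("stage 5/5: ANOVA vs ANCOVA power grid (reps=%d)", config.reps)
        base = TrialConfig(
            d=config.d,
            n_per_group=config.n_per_group,
            alpha=config.alpha,
            sides=config.sides,
            seed=_child_seed(config.seed, 4),
        )
        curve = power_grid(base, config.grid, reps=config.reps)
        artifacts["power_curve"] = write_csv(out / "power_curve.csv", curve, provenance)
        log.info("pipeline complete in %.1f s; artifacts in %s", time.perf_counter() - t0, out)
    finally:
        log.removeHandler(handler)
        handler.close()
    return artifacts
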