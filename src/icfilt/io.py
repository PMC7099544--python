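"""Image I/O, run configuration and the end-to-end comparison pipeline.

Single-channel float arrays are the internal currency.  Readers accept 8/16
bit grayscale PNG/TIFF, 32-bit float TIFF and whitespace-delimited text
matrices; colour input is collapsed to luminance with the Rec. 709 weights.
Writers export raw float TIFF and CSV matrices for analysis and min-max
normalised 8-bit PNG previews for display.

:func:`run_comparison` reproduces the full evaluation protocol for a set of
filters: filtered map, transfer-function map and k-space magnitude per
filter, pairwise image-space and k-space difference maps, inverse-Fourier
reconstructions through each filter map, histogram summaries of each
filtered map and its k-space magnitude, and a JSON manifest with a content
hash for every artifact.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

from . import spectral, stats_report
from .icf_engine import EvaluationPoint, compute_icf_image
from .reference_filters import (
    ConvolutionKernel,
    PSOConfig,
    default_hpf_kernel,
    pso_hpf,
    traditional_hpf,
    transfer_function_map,
)
from .synthetic_data import SyntheticSpec, generate

__all__ = [
    "RunConfig",
    "read_image",
    "write_image",
    "write_matrix",
    "normalize_for_display",
    "run_comparison",
]

_LUMA = np.array([0.2126, 0.7152, 0.0722])


def read_image(path) -> np.ndarray:
    """Load a 2D float grid from PNG/TIFF or a whitespace-delimited text matrix."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".txt", ".mat", ".dat", ".csv"):
            delimiter = "," if suffix == ".csv" else None
            arr = np.loadtxt(path, delimiter=delimiter, dtype=float)
        elif suffix in (".tif", ".tiff"):
            arr = tifffile.imread(path)
        elif suffix == ".png":
            arr = iio.imread(path)
        else:
            raise ValueError(f"unsupported image format: {suffix!r}")
    except (ValueError, FileNotFoundError):
        raise
    except Exception as exc:  # pragma: no cover - backend-specific failures
        raise ValueError(f"could not read {path}: {exc}") from exc
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        arr = arr @ _LUMA if arr.shape[2] == 3 else arr[:, :, 0]
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D grayscale image, got shape {arr.shape}")
    return np.atleast_2d(arr)


def normalize_for_display(arr: np.ndarray, dtype=np.uint8) -> np.ndarray:
    """Affine min-max rescale of a float map onto an integer display range."""
    arr = np.asarray(arr, dtype=float)
    info = np.iinfo(dtype)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros(arr.shape, dtype=dtype)
    scaled = (arr - lo) / (hi - lo) * info.max
    return np.round(scaled).astype(dtype)


def write_image(path, arr: np.ndarray) -> Path:
    """Write a float grid: 32-bit float TIFF (lossless) or normalised 8-bit PNG."""
    path = Path(path)
    arr = np.asarray(arr)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, arr.astype(np.float32))
    elif suffix == ".png":
        data = arr if arr.dtype in (np.uint8, np.uint16) else normalize_for_display(arr)
        iio.imwrite(path, data)
    else:
        raise ValueError(f"unsupported output format: {suffix!r}")
    return path


def write_matrix(path, arr: np.ndarray) -> Path:
    """Plain-text matrix export with full float precision (one row per line)."""
    path = Path(path)
    np.savetxt(path, np.asarray(arr, dtype=float), fmt="%.17g")
    return path


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one comparison run.

    Exactly one of ``input_path`` and ``synthetic`` supplies the image.
    ``filters`` selects any non-empty subset of {"icf", "traditional", "pso"}.
    """

    output_dir: Path
    input_path: Optional[Path] = None
    synthetic: Optional[SyntheticSpec] = None
    filters: Sequence[str] = ("icf", "traditional")
    evaluation_point: EvaluationPoint = EvaluationPoint()
    ein_fidelity: str = "canonical"
    neighbor_mode: str = "diagonal"
    degenerate_tol: Optional[float] = None
    prevalence_factor: float = 10.0
    kernel: Optional[ConvolutionKernel] = None
    pso: PSOConfig = PSOConfig()
    reconstruct_mode: str = "modulus"
    n_bins: int = 256
    seed: int = 0

    def validate(self) -> None:
        allowed = {"icf", "traditional", "pso"}
        if not self.filters or not set(self.filters) <= allowed:
            raise ValueError(f"filters must be a non-empty subset of {allowed}")
        if (self.input_path is None) == (self.synthetic is None):
            raise ValueError("provide exactly one of input_path or synthetic spec")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_comparison(cfg: RunConfig) -> Dict:
    """Run the selected filters on one image and write every artifact.

    Returns the manifest (also written as ``manifest.json``): per-filter
    filtered/TF/k-space maps, all pairwise image-space and k-space difference
    maps, reconstructions through each filter map, per-filter histogram
    summaries of the filtered map and of its k-space magnitude, resolved
    configuration and a SHA-256 hash per file.  Deterministic given the seed.
    """
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg.input_path is not None:
        image = read_image(cfg.input_path)
        source = str(cfg.input_path)
    else:
        image = generate(cfg.synthetic)
        source = f"synthetic:{cfg.synthetic.shape_kind}"

    artifacts: Dict[str, str] = {}

    def emit(name: str, arr: np.ndarray) -> None:
        artifacts[name] = str(write_matrix(outdir / f"{name}.csv", arr).name)

    emit("input", image)
    kernel = cfg.kernel or default_hpf_kernel()

    filtered: Dict[str, np.ndarray] = {}
    stage = "filtering"
    try:
        for name in cfg.filters:
            if name == "icf":
                res = compute_icf_image(
                    image,
                    pt=cfg.evaluation_point,
                    tol=cfg.degenerate_tol,
                    neighbor_mode=cfg.neighbor_mode,
                    fidelity=cfg.ein_fidelity,
                )
                filtered["icf"] = res.deltaE_map
                emit("icf_filtered", res.deltaE_map)
                emit("icf_tf", res.TF_map)
                emit("icf_degenerate_mask", res.degenerate_mask.astype(float))
            elif name == "traditional":
                hp = traditional_hpf(image, kernel)
                filtered["traditional"] = hp
                tf, _ = transfer_function_map(hp, image, tol=cfg.degenerate_tol)
                emit("traditional_filtered", hp)
                emit("traditional_tf", tf)
            elif name == "pso":
                target = traditional_hpf(image, kernel)
                pso_cfg = PSOConfig(
                    n_particles=cfg.pso.n_particles,
                    n_iterations=cfg.pso.n_iterations,
                    inertia=cfg.pso.inertia,
                    cognitive_weight=cfg.pso.cognitive_weight,
                    social_weight=cfg.pso.social_weight,
                    seed=cfg.seed if cfg.pso.seed == 0 else cfg.pso.seed,
                    tolerance=cfg.pso.tolerance,
                    patience=cfg.pso.patience,
                )
                hp, _state = pso_hpf(image, target, pso_cfg)
                filtered["pso"] = hp
                tf, _ = transfer_function_map(hp, image, tol=cfg.degenerate_tol)
                emit("pso_filtered", hp)
                emit("pso_tf", tf)

        stage = "spectral"
        spectra = {}
        for name, arr in filtered.items():
            grid = spectral.kspace_magnitude(arr)
            spectra[name] = grid.magnitude
            emit(f"{name}_kspace_magnitude", grid.magnitude)
            emit(
                f"{name}_reconstruction",
                spectral.reconstruct(arr, mode=cfg.reconstruct_mode),
            )

        stage = "difference maps"
        for a, b in itertools.combinations(filtered, 2):
            emit(f"diff_image_{a}_vs_{b}", spectral.difference_map(filtered[a], filtered[b]))
            emit(f"diff_kspace_{a}_vs_{b}", spectral.difference_map(spectra[a], spectra[b]))

        stage = "histogram summaries"
        summaries = {}
        for name in filtered:
            for domain, arr in (("image", filtered[name]), ("kspace", spectra[name])):
                summ = stats_report.summarize_image(arr, n_bins=cfg.n_bins)
                fname = f"summary_{name}_{domain}.csv"
                stats_report.write_summary_csv(summ, outdir / fname)
                artifacts[f"summary_{name}_{domain}"] = fname
                summaries[f"{name}_{domain}"] = {
                    "mu": summ.mu,
                    "sigma": summ.sigma,
                    "flagged": summ.flagged,
                }
    except Exception as exc:
        raise RuntimeError(f"comparison failed during {stage}: {exc}") from exc

    manifest = {
        "source": source,
        "seed": cfg.seed,
        "filters": list(cfg.filters),
        "config": {
            "evaluation_point": [cfg.evaluation_point.x, cfg.evaluation_point.y],
            "ein_fidelity": cfg.ein_fidelity,
            "neighbor_mode": cfg.neighbor_mode,
            "degenerate_tol": cfg.degenerate_tol,
            "prevalence_factor": cfg.prevalence_factor,
            "kernel": np.asarray(kernel.weights).tolist(),
            "pso": {
                "n_particles": cfg.pso.n_particles,
                "n_iterations": cfg.pso.n_iterations,
                "inertia": cfg.pso.inertia,
                "cognitive_weight": cfg.pso.cognitive_weight,
                "social_weight": cfg.pso.social_weight,
                "tolerance": cfg.pso.tolerance,
            },
            "reconstruct_mode": cfg.reconstruct_mode,
            "n_bins": cfg.n_bins,
        },
        "summaries": summaries,
        "artifacts": {
            name: {"file": fname, "sha256": _sha256(outdir / fname)}
            for name, fname in artifacts.items()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
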