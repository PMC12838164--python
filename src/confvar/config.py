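"""Declarative pipeline configuration (YAML) and seed bookkeeping.

One file configures every stage; every stage's RNG seed is derived
deterministically from the single global seed so reruns are reproducible
and subsets of the pipeline can be re-executed independently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .features import MotifSpec
from .spib import SpibConfig
from .synthetic import DEFAULT_CLASS_DISTRIBUTIONS, GeneratorConfig, Mixture

__all__ = ["PipelineConfig", "load_config", "stage_seed", "config_hash"]

# fixed per-stage offsets: stage seed = global seed + offset
_STAGE_OFFSETS = {
    "generate": 1, "extract": 2, "embed": 3, "landscape": 4,
    "classify": 5, "explain": 6, "stats": 7,
}


def stage_seed(global_seed: int, stage: str) -> int:
    if stage not in _STAGE_OFFSETS:
        raise KeyError(f"unknown stage {stage!r}")
    return (int(global_seed) + _STAGE_OFFSETS[stage]) % (2 ** 31 - 1)


@dataclass
class PipelineConfig:
    """All stage parameters; see data/example_config.yaml for the shipped
    defaults with commentary."""

    workdir: Path = Path("confvar_run")
    rng_seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    motif: MotifSpec | None = None            # None: use the toy topology's motif
    spib: SpibConfig = field(default_factory=SpibConfig)
    pca_components: int = 2
    landscape_bandwidth: float | str = "auto"
    landscape_grid_cells: int = 100
    landscape_temperature: float = 300.0
    hdbscan_min_cluster_size: int | None = None
    hdbscan_min_samples: int | None = None
    models: tuple[str, ...] = ("lr", "svm", "rf", "mlp", "xgb")
    n_bootstrap: int = 2000
    n_bootstrap_external: int = 1000
    decision_threshold: float = 0.5
    calibration_bins: int = 10
    background_size: int = 256
    stats_lo: float = 4.0
    stats_hi: float = 6.0
    baseline_scores: Path | None = None       # optional CSV of external predictors


def _mixture_from_dict(d: dict) -> Mixture:
    return Mixture(tuple(d["weights"]), tuple(d["means"]), tuple(d["sds"]))


def load_config(path: Path | str | None = None, seed: int | None = None,
                workdir: Path | str | None = None) -> PipelineConfig:
    """Load a YAML config; omitted keys keep package defaults. CLI-level
    ``seed``/``workdir`` override the file."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig()

    gen = raw.get("generator", {})
    dists = dict(DEFAULT_CLASS_DISTRIBUTIONS)
    for cls, spec in gen.get("class_distributions", {}).items():
        dists[cls] = {k: _mixture_from_dict(v) for k, v in spec.items()}
    cfg.generator = GeneratorConfig(
        variants=[tuple(v) for v in gen.get("variants", GeneratorConfig().variants)],
        n_depths=gen.get("n_depths", 2),
        n_seeds_per_depth=gen.get("n_seeds_per_depth", 5),
        n_frames_per_seed=gen.get("n_frames_per_seed", 256),
        class_distributions=dists,
        rng_seed=0,  # overwritten from the global seed at run time
    )
    if "motif" in raw:
        cfg.motif = MotifSpec(**raw["motif"])
    if "spib" in raw:
        cfg.spib = SpibConfig(**raw["spib"])
    emb = raw.get("embedding", {})
    cfg.pca_components = emb.get("pca_components", 2)
    lsc = raw.get("landscape", {})
    cfg.landscape_bandwidth = lsc.get("bandwidth", "auto")
    cfg.landscape_grid_cells = lsc.get("grid_cells", 100)
    cfg.landscape_temperature = lsc.get("temperature", 300.0)
    cfg.hdbscan_min_cluster_size = lsc.get("min_cluster_size")
    cfg.hdbscan_min_samples = lsc.get("min_samples")
    clf = raw.get("classify", {})
    cfg.models = tuple(clf.get("models", cfg.models))
    cfg.n_bootstrap = clf.get("n_bootstrap", 2000)
    cfg.n_bootstrap_external = clf.get("n_bootstrap_external", 1000)
    cfg.decision_threshold = clf.get("threshold", 0.5)
    cfg.calibration_bins = clf.get("calibration_bins", 10)
    cfg.background_size = raw.get("attribution", {}).get("background_size", 256)
    st = raw.get("stats", {})
    cfg.stats_lo = st.get("intact_below", 4.0)
    cfg.stats_hi = st.get("disrupted_above", 6.0)
    io = raw.get("io", {})
    cfg.workdir = Path(io.get("workdir", "confvar_run"))
    if io.get("baseline_scores"):
        cfg.baseline_scores = Path(io["baseline_scores"])
    cfg.rng_seed = int(raw.get("rng_seed", 0))

    if seed is not None:
        cfg.rng_seed = int(seed)
    if workdir is not None:
        cfg.workdir = Path(workdir)
    cfg.generator.rng_seed = stage_seed(cfg.rng_seed, "generate")
    cfg.spib.rng_seed = stage_seed(cfg.rng_seed, "embed")
    return cfg


def config_hash(cfg: PipelineConfig) -> str:
    """Stable digest of the configuration for the run manifest."""
    def default(o):
        if isinstance(o, Path):
            return str(o)
        if hasattr(o, "__dict__"):
            return vars(o)
        if isinstance(o, tuple):
            return list(o)
        return str(o)

    blob = json.dumps(asdict_safe(cfg), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def asdict_safe(cfg: PipelineConfig) -> dict:
    out = {}
    for k, v in vars(cfg).items():
        try:
            out[k] = asdict(v) if hasattr(v, "__dataclass_fields__") else v
        except TypeError:
            out[k] = str(v)
    return out
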