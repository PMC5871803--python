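"""End-to-end analysis pipeline: root systems -> segment table ->
traits + barcodes -> bottleneck matrix -> NMDS (and PCA on traits).

A run is driven by a small configuration (YAML file or dict) naming
either an RSML input directory or simulation preset blocks, and writes
every intermediate product as CSV into a run directory, together with a
log and a machine-readable manifest (seed, file hashes).  Rerunning
with the same configuration and seed reproduces all outputs
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import ordination, persistence, rsml, segments, simulate, traits
from .fitter import tree_fitter_indices
from .tree import RootSystemTree

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``rsml_dir`` or ``presets`` must be given.
    ``presets`` maps preset name -> number of replicates.
    """
    out_dir: str
    seed: int = 0
    rsml_dir: str | None = None
    presets: dict[str, int] | None = None
    nmds_dimensions: int = 2
    nmds_restarts: int = 20

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _load_trees(config: RunConfig, run_dir: Path) -> list[RootSystemTree]:
    if (config.rsml_dir is None) == (config.presets is None):
        raise ValueError("config must name either rsml_dir or presets")
    if config.rsml_dir is not None:
        trees = []
        for path in sorted(Path(config.rsml_dir).glob("*.rsml")):
            trees.extend(rsml.read_rsml(path))
        if not trees:
            raise ValueError(f"no RSML files found in {config.rsml_dir}")
        return trees
    all_presets = simulate.load_presets()
    trees = []
    idx = 0
    sim_dir = run_dir / "rsml"
    sim_dir.mkdir(exist_ok=True)
    for name, reps in config.presets.items():
        params = all_presets[name]
        for rep in range(1, reps + 1):
            s = simulate._replicate_seed(config.seed, idx)
            idx += 1
            tree = simulate.generate(params, s, plant_id=f"{name}_{rep:02d}")
            rsml.write_rsml([tree], sim_dir / f"{name}_{rep:02d}.rsml")
            trees.append(tree)
    return trees


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and return the run directory.

    Outputs: ``segments.csv``, ``traits.csv``, ``barcodes/<plant>.csv``,
    ``bottleneck.csv``, ``nmds.csv``, ``pca.csv``, ``run.log`` and
    ``manifest.json``.  Any stage error aborts the run; partial outputs
    are kept next to a ``FAILED`` marker naming the stage.
    """
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    log_path = run_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root_logger = logging.getLogger("roottopo")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)
    timings: dict[str, float] = {}
    stage = "setup"
    try:
        import importlib.metadata
        try:
            version = importlib.metadata.version("roottopo")
        except importlib.metadata.PackageNotFoundError:
            version = "unknown"
        logger.info("roottopo %s, seed %d", version, config.seed)

        def timed(name):
            timings[name] = time.perf_counter()
            logger.info("stage %s started", name)
            return name

        stage = timed("input")
        trees = _load_trees(config, run_dir)
        timings["input"] = time.perf_counter() - timings["input"]

        stage = timed("segment_table")
        table = segments.build_segment_table(trees)
        segments.write_table(table, run_dir / "segments.csv")
        timings["segment_table"] = time.perf_counter() - timings["segment_table"]

        stage = timed("traits")
        idx = {t.plant_id: tree_fitter_indices(t) for t in trees}
        tmat = traits.trait_matrix(table, indices=idx)
        traits.write_traits(tmat, run_dir / "traits.csv")
        timings["traits"] = time.perf_counter() - timings["traits"]

        stage = timed("barcodes")
        barcodes = persistence.compute_barcodes(table)
        bdir = run_dir / "barcodes"
        bdir.mkdir(exist_ok=True)
        for b in barcodes:
            persistence.write_barcode(b, bdir / f"{b.source_id}.csv")
        timings["barcodes"] = time.perf_counter() - timings["barcodes"]

        stage = timed("bottleneck")
        matrix = persistence.pairwise_bottleneck(barcodes)
        persistence.write_matrix(matrix, run_dir / "bottleneck.csv")
        timings["bottleneck"] = time.perf_counter() - timings["bottleneck"]

        stage = timed("nmds")
        nmds = ordination.ordinate_nmds(
            matrix, k=config.nmds_dimensions, seed=config.seed,
            n_restarts=config.nmds_restarts)
        nmds.to_frame().to_csv(run_dir / "nmds.csv", index_label="plant")
        timings["nmds"] = time.perf_counter() - timings["nmds"]

        stage = timed("pca")
        pca = ordination.ordinate_pca(tmat.dropna(axis=1, how="any"))
        out = pca.to_frame()
        out.to_csv(run_dir / "pca.csv", index_label="plant")
        timings["pca"] = time.perf_counter() - timings["pca"]

        manifest = {
            "seed": config.seed,
            "version": version,
            "n_plants": len(trees),
            "nmds_stress": nmds.stress,
            "pca_explained_variance": [float(v) for v in
                                       pca.explained_variance[:2]],
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
            "files": {p.name: _sha256(p) for p in sorted(run_dir.glob("*.csv"))},
        }
        (run_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
        logger.info("run complete: %s", run_dir)
        return run_dir
    except Exception as exc:
        plant = getattr(exc, "plant", "")
        (run_dir / "FAILED").write_text(f"stage: {stage}\n{plant}\n{exc}\n")
        logger.error("stage %s failed: %s", stage, exc)
        raise
    finally:
        root_logger.removeHandler(handler)
        handler.close()
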