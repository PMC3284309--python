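"""File formats, packaged fixtures, and the end-to-end validation protocol.

Trajectories travel as multi-model PDB (one MODEL per frame, particles as
CA atoms of sequential GLY residues on chain A) or as plain-text coordinate
tables (one ``x y z`` line per particle, frames separated by blank lines).
Dissimilarity matrices and per-frame label tables are CSV; run reports are
JSON.  The packaged FG-nucleoporin amino-acid sequences (GLFG, FxFG, SxSG)
ship as FASTA fixtures.

:func:`run_protocol` executes the full validation pipeline on one model:
generate the ensemble, build the dissimilarity matrix, cluster at each
requested k, compute diagnostics, and classify states — writing every
artifact plus a reproducibility log.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import analytic_models, chain_models, cluster_diagnostics, helix_dynamics
from .analytic_models import AnalyticModelParams, save_matrix_csv
from .containers import (InvalidInputError, InvalidParameterError,
                         StructureEnsemble)
from .spectral_clustering import DEFAULT_Q, spectral_cluster
from .structure_metrics import pairwise_rmsd_matrix

__all__ = [
    "RunConfig",
    "read_trajectory",
    "write_trajectory",
    "load_fg_nup_sequence",
    "run_protocol",
]

log = logging.getLogger("polyclust")

DEFAULT_K_LIST = (3, 5, 10, 15)
MODELS = ("linear", "sinusoid", "rotation", "cyclical", "dynamic")
FG_NUP_NAMES = ("glfg", "fxfg", "sxsg")


@dataclass
class RunConfig:
    """Configuration of one validation-protocol run.

    Either ``model`` (one of linear / sinusoid / rotation / cyclical /
    dynamic) or ``input_path`` (a trajectory file) must be given.
    """

    model: str | None = None
    input_path: str | None = None
    input_format: str = "pdb"
    n: int = 1000
    z: float = analytic_models.DEFAULT_Z
    cycles: int = 3
    k_list: tuple[int, ...] = DEFAULT_K_LIST
    q: int = DEFAULT_Q
    seed: int = 0
    out_dir: str = "polyclust_out"
    whisker_style: str = "median-quartile"

    def __post_init__(self) -> None:
        if (self.model is None) == (self.input_path is None):
            raise InvalidParameterError(
                "exactly one of model or input_path must be set"
            )
        if self.model is not None and self.model not in MODELS:
            raise InvalidParameterError(
                f"unknown model {self.model!r}; choose from {MODELS}"
            )
        if not self.k_list:
            raise InvalidParameterError("k_list must be nonempty")
        for k in self.k_list:
            if not 2 <= k <= self.n:
                raise InvalidParameterError(f"each k must be in [2, n]; got {k}")
        if self.q < 1:
            raise InvalidParameterError("q must be >= 1")


# --------------------------------------------------------------------------
# sequence fixtures


def load_fg_nup_sequence(name: str) -> str:
    """Packaged FG-nup amino-acid sequence (``glfg``, ``fxfg`` or ``sxsg``)."""
    name = name.lower()
    if name not in FG_NUP_NAMES:
        raise InvalidParameterError(
            f"unknown sequence {name!r}; choose from {FG_NUP_NAMES}"
        )
    text = (importlib.resources.files("polyclust.data") / f"{name}.fasta").read_text()
    return "".join(line.strip() for line in text.splitlines()
                   if line and not line.startswith(">"))


# --------------------------------------------------------------------------
# trajectory formats


def _read_pdb(path) -> StructureEnsemble:
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    frames = []
    for m in range(1, n_models + 1):
        atoms = pdb.get_structure(model=m)
        ca = atoms[atoms.atom_name == "CA"]
        if ca.array_length() == 0:
            raise InvalidInputError(f"frame {m}: no CA atoms found in {path}")
        frames.append(np.asarray(ca.coord, dtype=np.float64))
        if len(frames[-1]) != len(frames[0]):
            raise InvalidInputError(
                f"frame {m}: {len(frames[-1])} CA atoms, expected "
                f"{len(frames[0])} (inconsistent particle counts)"
            )
    return StructureEnsemble(np.stack(frames))


def _read_xyz_table(path) -> StructureEnsemble:
    frames: list[list[list[float]]] = [[]]
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                if frames[-1]:
                    frames.append([])
                continue
            parts = stripped.split()
            if len(parts) != 3:
                raise InvalidInputError(
                    f"{path}:{lineno}: expected 3 coordinates, got {len(parts)}"
                )
            frames[-1].append([float(p) for p in parts])
    if not frames[-1]:
        frames.pop()
    if not frames:
        raise InvalidInputError(f"{path}: no frames found")
    counts = {len(f) for f in frames}
    if len(counts) > 1:
        bad = next(i for i, f in enumerate(frames, 1)
                   if len(f) != len(frames[0]))
        raise InvalidInputError(
            f"frame {bad}: inconsistent particle count in {path}"
        )
    return StructureEnsemble(np.asarray(frames, dtype=np.float64))


def read_trajectory(path, format: str = "pdb") -> StructureEnsemble:
    """Read a trajectory from multi-model PDB or a plain-text xyz table."""
    if format == "pdb":
        return _read_pdb(path)
    if format in ("xyz", "xyz-table"):
        return _read_xyz_table(path)
    raise InvalidParameterError(f"unknown trajectory format {format!r}")


def _write_pdb(ensemble: StructureEnsemble, path) -> None:
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = ensemble.n_particles
    stack = struc.AtomArrayStack(ensemble.n_frames, n)
    stack.coord = ensemble.coordinates.astype(np.float32)
    stack.chain_id = np.full(n, "A")
    stack.res_id = np.arange(1, n + 1)
    stack.res_name = np.full(n, "GLY")
    stack.atom_name = np.full(n, "CA")
    stack.element = np.full(n, "C")
    stack.hetero = np.full(n, False)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def _write_xyz_table(ensemble: StructureEnsemble, path) -> None:
    with open(path, "w") as fh:
        for f, frame in enumerate(ensemble.coordinates):
            if f:
                fh.write("\n")
            for x, y, z in frame:
                fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")


def write_trajectory(ensemble: StructureEnsemble, path,
                     format: str = "pdb") -> None:
    """Write a trajectory as multi-model PDB or a plain-text xyz table."""
    if format == "pdb":
        _write_pdb(ensemble, path)
    elif format in ("xyz", "xyz-table"):
        _write_xyz_table(ensemble, path)
    else:
        raise InvalidParameterError(f"unknown trajectory format {format!r}")


# --------------------------------------------------------------------------
# model generation and the full protocol


def generate_model(config: RunConfig
                   ) -> tuple[np.ndarray | None, StructureEnsemble | None]:
    """Generate the requested model; returns ``(matrix, ensemble)``.

    Analytic models yield a dissimilarity matrix directly (no coordinates);
    geometric and dynamic models yield an ensemble (matrix computed later).
    """
    params = AnalyticModelParams(n=config.n, z=config.z)
    if config.model == "linear":
        return analytic_models.linear_dissimilarity(params), None
    if config.model == "sinusoid":
        return analytic_models.sinusoid_dissimilarity(params), None
    if config.model == "rotation":
        return None, chain_models.rotation_ensemble(config.n)
    if config.model == "cyclical":
        return None, chain_models.cyclical_ensemble(config.n, cycles=config.cycles)
    if config.model == "dynamic":
        _, _, concat = helix_dynamics.run_fold_unfold(config.seed)
        return None, concat
    raise InvalidParameterError(f"unknown model {config.model!r}")


def labels_frame(result, frame_times=None) -> pd.DataFrame:
    """Tidy per-frame table: frame, k, cluster label, sigma."""
    n = len(result.labels)
    if frame_times is None:
        frame_times = np.arange(1, n + 1)
    return pd.DataFrame({
        "frame": frame_times,
        "k": result.k,
        "label": result.labels,
        "sigma": result.sigma.sigma if result.sigma is not None else np.nan,
    })


def diagnostics_frame(diags, k: int) -> pd.DataFrame:
    """Tidy per-cluster table of the diagnostics for one k."""
    rows = []
    for d in diags:
        row = {"k": k, "cluster": d.cluster_id, "size": d.size,
               "median_time": d.median_time, "state": d.state}
        for name, summ in (("rmsd", d.intra_rmsd), ("sigma", d.intra_sigma),
                           ("rg", d.rg)):
            if summ is None:
                continue
            row.update({f"{name}_q1": summ.q1, f"{name}_median": summ.median,
                        f"{name}_q3": summ.q3, f"{name}_notch": summ.notch_halfwidth,
                        f"{name}_n_outliers": len(summ.outliers)})
        rows.append(row)
    return pd.DataFrame(rows)


def run_protocol(config: RunConfig) -> dict:
    """Execute the full validation protocol and write all artifacts.

    Pipeline: generate (or load) the ensemble, build the dissimilarity
    matrix, spectrally cluster at each k, compute diagnostics, classify
    states.  Artifacts in ``out_dir``: the matrix CSV, one label CSV per k,
    a combined diagnostics CSV, a JSON report, and a run log.  Reproducible
    from the logged config and seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()
    try:
        log.info("stage=config %s", json.dumps(dataclasses.asdict(config)))
        if config.model is not None:
            log.info("stage=generate model=%s n=%d", config.model, config.n)
            X, ensemble = generate_model(config)
        else:
            log.info("stage=load path=%s", config.input_path)
            X, ensemble = None, read_trajectory(config.input_path,
                                               config.input_format)
        if X is None:
            log.info("stage=distmat frames=%d", ensemble.n_frames)
            X = pairwise_rmsd_matrix(ensemble)
        save_matrix_csv(X, out / "distance_matrix.csv")

        report = {
            "config": dataclasses.asdict(config),
            "n_frames": int(X.shape[0]),
            "results": {},
        }
        diag_tables = []
        for k in config.k_list:
            log.info("stage=cluster k=%d", k)
            result = spectral_cluster(X, k, q=config.q, seed=config.seed)
            labels_frame(result).to_csv(out / f"labels_k{k}.csv", index=False)
            diags = cluster_diagnostics.compute_diagnostics(
                X, result, ensemble, whisker_style=config.whisker_style)
            diag_tables.append(diagnostics_frame(diags, k))
            report["results"][str(k)] = {
                "objective": result.objective,
                "sizes": [int(d.size) for d in diags],
                "states": {str(d.cluster_id): d.state for d in diags},
                "n_meta_stable": sum(d.state == "meta-stable" for d in diags),
                "n_transition": sum(d.state == "transition" for d in diags),
                "representatives": {
                    str(d.cluster_id): cluster_diagnostics.representative_structure(
                        X, result, d.cluster_id)
                    for d in diags},
            }
        pd.concat(diag_tables, ignore_index=True).to_csv(
            out / "diagnostics.csv", index=False)
        report["elapsed_s"] = time.time() - t0
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        log.info("stage=done elapsed=%.1fs", report["elapsed_s"])
        return report
    except Exception:
        log.exception("protocol failed")
        raise
    finally:
        log.removeHandler(handler)
        handler.close()
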