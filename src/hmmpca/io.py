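"""Dataset and model persistence.

Datasets travel as delimited matrices (rows = time, columns = regions) with
a companion sessions file of 1-based start indices, one per line.  Models
and ground truth are stored as HDF5 bundles whose root attributes carry JSON
metadata (kind, hyperparameters, seed, convergence record), so a fit is
re-runnable from its bundle alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import numpy as np

from .models import (
    FitOptions,
    HMMGaussianModel,
    HMMPCAModel,
    MixPCAModel,
    TimeSeriesDataset,
)
from .ppca import PPCAState
from .simulate import GroundTruth

__all__ = [
    "read_dataset",
    "write_dataset",
    "save_model",
    "load_model",
    "save_ground_truth",
    "load_ground_truth",
]

logger = logging.getLogger("hmmpca")

BUNDLE_VERSION = 1

_KINDS = {
    HMMPCAModel: "hmm-pca",
    MixPCAModel: "mix-pca",
    HMMGaussianModel: "hmm-gauss",
}


def read_dataset(
    path: str | Path,
    sessions_path: str | Path | None = None,
    standardize: bool = False,
) -> TimeSeriesDataset:
    """Load a delimited (time x regions) matrix plus session boundaries.

    The delimiter is sniffed (comma or whitespace).  A missing sessions file
    means a single session.  NaN or ragged rows raise errors naming the
    offending line.
    """
    path = Path(path)
    rows: list[list[float]] = []
    labels: list[str] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if lineno == 1:
                try:
                    [float(x) for x in parts]
                except ValueError:
                    labels = parts
                    continue
            try:
                vals = [float(x) for x in parts]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value ({exc})")
            if rows and len(vals) != len(rows[0]):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(rows[0])} columns, got {len(vals)}"
                )
            for col, v in enumerate(vals, start=1):
                if not np.isfinite(v):
                    raise ValueError(f"{path}:{lineno}: non-finite value in column {col}")
            rows.append(vals)
    values = np.asarray(rows, dtype=float)
    if sessions_path is None:
        logger.warning("no sessions file given; assuming a single session")
        starts = [1]
    else:
        with open(sessions_path) as fh:
            starts = [int(line) for line in fh.read().split()]
    return_ds = TimeSeriesDataset(values, starts, labels)
    return return_ds.standardized() if standardize else return_ds


def write_dataset(
    data: TimeSeriesDataset, path: str | Path, sessions_path: str | Path
) -> None:
    """Write a dataset as CSV plus a sessions file (1-based start indices)."""
    header = ",".join(data.region_labels) if data.region_labels else ""
    np.savetxt(path, data.values, delimiter=",", header=header, comments="")
    Path(sessions_path).write_text(
        "\n".join(str(s) for s in data.session_starts) + "\n"
    )


def _options_dict(opts: FitOptions | None) -> dict:
    if opts is None:
        return {}
    return {
        k: v
        for k, v in vars(opts).items()
        if k != "initial_gamma" and not isinstance(v, np.ndarray)
    }


def save_model(model, path: str | Path, gamma: np.ndarray | None = None) -> None:
    """Persist a fitted model (and optionally its state time courses)."""
    kind = _KINDS.get(type(model))
    if kind is None:
        raise TypeError(f"cannot serialise {type(model).__name__}")
    meta = {
        "version": BUNDLE_VERSION,
        "kind": kind,
        "n_states": model.n_states,
        "converged": bool(model.converged),
        "dead_states": list(model.dead_states),
        "options": _options_dict(model.config),
    }
    with h5py.File(path, "w") as f:
        f.attrs["metadata"] = json.dumps(meta)
        f.create_dataset("fit_trace", data=np.asarray(model.fit_trace, dtype=float))
        if isinstance(model, (HMMPCAModel, MixPCAModel)):
            for k, st in enumerate(model.states):
                f.create_dataset(f"states/{k}/loadings", data=st.loadings)
                f.attrs[f"noise_variance_{k}"] = st.noise_variance
        else:
            for k, S in enumerate(model.states):
                f.create_dataset(f"states/{k}/covariance", data=np.asarray(S))
            if model.projection is not None:
                for key, val in model.projection.items():
                    f.create_dataset(f"projection/{key}", data=np.asarray(val))
        if isinstance(model, MixPCAModel):
            f.create_dataset("weights", data=model.weights)
        else:
            f.create_dataset("transition", data=model.transition)
            f.create_dataset("initial", data=model.initial)
        if gamma is not None:
            f.create_dataset("gamma", data=np.asarray(gamma, dtype=float))


def load_model(path: str | Path, expect_kind: str | None = None):
    """Load a model bundle; returns (model, gamma-or-None).

    ``expect_kind`` guards callers that only handle one family; a mismatch
    raises instead of silently mis-interpreting the arrays.
    """
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["metadata"])
        if meta.get("version") != BUNDLE_VERSION:
            raise ValueError(
                f"bundle version {meta.get('version')} not supported "
                f"(expected {BUNDLE_VERSION}); re-fit or upgrade the bundle"
            )
        kind = meta["kind"]
        if expect_kind is not None and kind != expect_kind:
            raise ValueError(f"expected a {expect_kind} bundle, found {kind}")
        opts = FitOptions(**meta["options"]) if meta["options"] else None
        trace = list(f["fit_trace"][()])
        K = meta["n_states"]
        gamma = f["gamma"][()] if "gamma" in f else None
        common = dict(
            fit_trace=trace,
            config=opts,
            converged=meta["converged"],
            dead_states=list(meta["dead_states"]),
        )
        if kind in ("hmm-pca", "mix-pca"):
            states = [
                PPCAState(
                    f[f"states/{k}/loadings"][()],
                    float(f.attrs[f"noise_variance_{k}"]),
                )
                for k in range(K)
            ]
            if kind == "mix-pca":
                model = MixPCAModel(states=states, weights=f["weights"][()], **common)
            else:
                model = HMMPCAModel(
                    states=states,
                    transition=f["transition"][()],
                    initial=f["initial"][()],
                    **common,
                )
        else:
            states = [f[f"states/{k}/covariance"][()] for k in range(K)]
            projection = None
            if "projection" in f:
                projection = {key: f[f"projection/{key}"][()] for key in f["projection"]}
            model = HMMGaussianModel(
                states=states,
                transition=f["transition"][()],
                initial=f["initial"][()],
                projection=projection,
                **common,
            )
    return model, gamma


def save_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    """Serialise a generator's ground truth (JSON metadata + arrays)."""
    scalars = {
        k: v
        for k, v in truth.generator_config.items()
        if not isinstance(v, (np.ndarray, list, dict))
    }
    with h5py.File(path, "w") as f:
        f.attrs["metadata"] = json.dumps(
            {"version": BUNDLE_VERSION, "config": scalars}
        )
        f.create_dataset("state_path", data=truth.state_path)
        f.create_dataset("transition", data=truth.transition)
        for k, C in enumerate(truth.state_covariances):
            f.create_dataset(f"state_covariances/{k}", data=C)
        for key, val in truth.generator_config.items():
            if isinstance(val, np.ndarray):
                f.create_dataset(f"config/{key}", data=val)


def load_ground_truth(path: str | Path) -> GroundTruth:
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["metadata"])
        config = dict(meta["config"])
        if "config" in f:
            for key in f["config"]:
                config[key] = f[f"config/{key}"][()]
        K = len(f["state_covariances"])
        return GroundTruth(
            state_path=f["state_path"][()],
            state_covariances=[f[f"state_covariances/{k}"][()] for k in range(K)],
            transition=f["transition"][()],
            generator_config=config,
        )
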