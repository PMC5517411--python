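"""Serialization: TSV + JSON-sidecar series, HDF5 containers, graph exports."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd

from .cohort import GroupTruth, make_session_design
from .errors import ValidationError
from .simulate import SessionSeries
from .spdcm import DcmPosterior, PriorDensity
from .spectra import SpectralData


def write_series(series: SessionSeries, path: str | Path, extra_meta: dict | None = None):
    """Write a session as TSV (columns = regions) with a JSON sidecar."""
    path = Path(path)
    series.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")
    meta = {"tr": series.tr, "region_names": series.region_names}
    meta.update(extra_meta or {})
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def read_series(path: str | Path) -> SessionSeries:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise ValidationError(f"missing JSON sidecar for {path}")
    meta = json.loads(sidecar.read_text())
    frame = pd.read_csv(path, sep="\t")
    return SessionSeries(
        data=frame.to_numpy(dtype=float),
        tr=float(meta["tr"]),
        region_names=list(meta.get("region_names", frame.columns)),
    )


def write_confounds(confounds: pd.DataFrame, path: str | Path):
    confounds.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_confounds(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_truth(truth: GroupTruth, path: str | Path):
    with h5py.File(path, "w") as f:
        f.create_dataset("beta3", data=truth.beta3)
        f.create_dataset("beta2", data=truth.beta2)
        f.create_dataset("theta", data=truth.theta)
        f.attrs["sigma2"] = truth.sigma2
        f.attrs["sigma3"] = truth.sigma3
        if truth.seed is not None:
            f.attrs["seed"] = truth.seed
        f.attrs["region_names"] = json.dumps(truth.region_names)
        f.attrs["score_coupling"] = json.dumps(
            [[i, k, g] for (i, k), g in truth.score_coupling.items()]
        )


def load_truth(path: str | Path) -> GroupTruth:
    with h5py.File(path, "r") as f:
        coupling = {
            (int(i), int(k)): float(g)
            for i, k, g in json.loads(f.attrs["score_coupling"])
        }
        return GroupTruth(
            beta3=f["beta3"][()],
            beta2=f["beta2"][()],
            theta=f["theta"][()],
            sigma2=float(f.attrs["sigma2"]),
            sigma3=float(f.attrs["sigma3"]),
            score_coupling=coupling,
            design=make_session_design(4),
            region_names=list(json.loads(f.attrs["region_names"])),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )


def save_spectral(sd: SpectralData, path: str | Path):
    with h5py.File(path, "w") as f:
        f.create_dataset("freqs", data=sd.freqs)
        f.create_dataset("csd_real", data=sd.csd.real)
        f.create_dataset("csd_imag", data=sd.csd.imag)
        f.attrs["region_names"] = json.dumps(sd.region_names)
        f.attrs["meta"] = json.dumps(sd.meta, default=str)


def load_spectral(path: str | Path) -> SpectralData:
    with h5py.File(path, "r") as f:
        return SpectralData(
            freqs=f["freqs"][()],
            csd=f["csd_real"][()] + 1j * f["csd_imag"][()],
            region_names=list(json.loads(f.attrs["region_names"])),
            meta=json.loads(f.attrs["meta"]),
        )


def save_posterior(post: DcmPosterior, path: str | Path):
    with h5py.File(path, "w") as f:
        f.create_dataset("mean", data=post.mean)
        f.create_dataset("cov", data=post.cov)
        f.create_dataset("prior_mean", data=post.prior.mean)
        f.create_dataset("prior_variance", data=post.prior.variance)
        f.attrs["free_energy"] = post.free_energy
        f.attrs["n_regions"] = post.n_regions
        f.attrs["meta"] = json.dumps(post.meta, default=str)


def load_posterior(path: str | Path) -> DcmPosterior:
    with h5py.File(path, "r") as f:
        return DcmPosterior(
            mean=f["mean"][()],
            cov=f["cov"][()],
            free_energy=float(f.attrs["free_energy"]),
            prior=PriorDensity(
                mean=f["prior_mean"][()], variance=f["prior_variance"][()]
            ),
            n_regions=int(f.attrs["n_regions"]),
            meta=json.loads(f.attrs["meta"]),
        )


def save_peb(peb, path: str | Path):
    """Persist a PEB posterior (design, carried set, labels included)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("beta_mean", data=peb.beta_mean)
        f.create_dataset("beta_cov", data=peb.beta_cov)
        f.create_dataset("design", data=np.asarray(peb.design.values, dtype=float))
        f.create_dataset("carried", data=np.asarray(peb.carried, dtype=int))
        f.attrs["gamma"] = peb.gamma
        f.attrs["free_energy"] = peb.free_energy
        f.attrs["effect_names"] = json.dumps(list(peb.design.effect_names))
        f.attrs["unit_names"] = json.dumps(list(peb.design.unit_names))
        f.attrs["param_labels"] = json.dumps(list(peb.param_labels))
        f.attrs["meta"] = json.dumps(peb.meta, default=str)


def load_peb(path: str | Path):
    from types import SimpleNamespace

    from .peb import PebPosterior

    with h5py.File(path, "r") as f:
        design = SimpleNamespace(
            values=f["design"][()],
            effect_names=json.loads(f.attrs["effect_names"]),
            unit_names=json.loads(f.attrs["unit_names"]),
        )
        return PebPosterior(
            beta_mean=f["beta_mean"][()],
            beta_cov=f["beta_cov"][()],
            gamma=float(f.attrs["gamma"]),
            free_energy=float(f.attrs["free_energy"]),
            design=design,
            carried=f["carried"][()],
            param_labels=json.loads(f.attrs["param_labels"]),
            meta=json.loads(f.attrs["meta"]),
        )


def save_voxels(blocks: dict[str, np.ndarray], path: str | Path):
    with h5py.File(path, "w") as f:
        for name, block in blocks.items():
            f.create_dataset(name, data=block)


def effect_graph(table: pd.DataFrame, effect: str) -> nx.DiGraph:
    """Directed graph of surviving between-region effects of one type."""
    g = nx.DiGraph(effect=effect)
    sub = table[(table["effect"] == effect) & table["survives"] & (table["source"] != "")]
    for _, row in sub.iterrows():
        if row["source"] == row["target"]:
            continue
        g.add_edge(
            row["source"],
            row["target"],
            weight=float(row["mean"]),
            sign="+" if row["mean"] > 0 else "-",
        )
    return g


def write_dot(g: nx.DiGraph, path: str | Path):
    """Minimal Graphviz DOT writer (edge labels carry effect sizes)."""
    lines = ["digraph effects {"]
    for node in g.nodes:
        lines.append(f'  "{node}";')
    for u, v, d in g.edges(data=True):
        lines.append(f'  "{u}" -> "{v}" [label="{d.get("weight", 0):+.3f}"];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
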