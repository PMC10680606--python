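"""Readers and writers for the package's on-disk formats.

Networks travel as a 3-column edge-list TSV (regulator_id, target_id,
signed K) plus a 2-column node/layer TSV; the simulator-dialect "targets
file" (target, #regulators, regulator ids, K values, Hill coefficients) and
"master regulators file" (MR id, per-condition rates) are also supported.
Expression matrices are TSV with a header row of condition ids and a sidecar
TSV of layer tags.  Model checkpoints are a single NPZ holding weights,
batchnorm statistics, architecture hyperparameters and the featurization
settings, so a checkpoint fully determines preprocessing at inference.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConsistencyError, ParameterError
from .features import FeaturizationParams
from .generate import TopologyParams
from .network import ExpressionMatrix, MRProfileSet, RegulatoryNetwork
from .nn import MLNet, SPNet
from .simulate import SimulationParams
from .train import TrainingConfig


# ------------------------------------------------------------------- networks
def write_network(net: RegulatoryNetwork, edges_path, nodes_path) -> None:
    ids = net.node_ids
    K = net.K if net.K is not None else np.full(net.n_edges, np.nan)
    pd.DataFrame(
        {
            "regulator_id": [ids[r] for r in net.edges[:, 0]],
            "target_id": [ids[t] for t in net.edges[:, 1]],
            "K": K,
        }
    ).to_csv(edges_path, sep="\t", index=False)
    pd.DataFrame({"node_id": ids, "layer": net.layers}).to_csv(nodes_path, sep="\t", index=False)


def read_network(edges_path, nodes_path, hill=None) -> RegulatoryNetwork:
    nodes = pd.read_csv(nodes_path, sep="\t")
    counts = nodes["layer"].value_counts()
    n_mr, n_tf, n_g = int(counts.get("MR", 0)), int(counts.get("TF", 0)), int(counts.get("G", 0))
    index = {nid: i for i, nid in enumerate(nodes["node_id"])}
    edges_df = pd.read_csv(edges_path, sep="\t")
    edges = np.array(
        [[index[r], index[t]] for r, t in zip(edges_df["regulator_id"], edges_df["target_id"])],
        dtype=np.int64,
    ).reshape(-1, 2)
    K = edges_df["K"].to_numpy(dtype=float)
    if np.isnan(K).all():
        K = None
    net = RegulatoryNetwork(n_mr, n_tf, n_g, edges, K=K, hill=hill)
    net.validate()
    return net


def write_targets_file(net: RegulatoryNetwork, path) -> None:
    """Simulator-dialect record per regulated node: id, #regs, reg ids, Ks, Hills."""
    if not net.parameterized:
        raise ConsistencyError("network lacks K / Hill assignments")
    ids = net.node_ids
    by_target: dict[int, list[int]] = {}
    for e, (reg, tgt) in enumerate(net.edges):
        by_target.setdefault(int(tgt), []).append(e)
    with open(path, "w") as fh:
        for tgt in sorted(by_target):
            es = by_target[tgt]
            rec = (
                [ids[tgt], str(len(es))]
                + [ids[net.edges[e, 0]] for e in es]
                + [f"{net.K[e]:.6g}" for e in es]
                + [str(int(net.hill[e])) for e in es]
            )
            fh.write(",".join(rec) + "\n")


def write_master_regulators_file(net: RegulatoryNetwork, profiles: MRProfileSet, path) -> None:
    """One record per MR: id followed by its production rate in every condition."""
    ids = net.node_ids
    with open(path, "w") as fh:
        for j in range(profiles.n_mr):
            fh.write(",".join([ids[j]] + [f"{v:.6g}" for v in profiles.rates[:, j]]) + "\n")


# ---------------------------------------------------------------- expression
def write_expression(expr: ExpressionMatrix, path, layers_path=None) -> None:
    df = pd.DataFrame(expr.values, index=expr.row_ids, columns=expr.condition_ids)
    df.index.name = "row_id"
    df.to_csv(path, sep="\t")
    if layers_path is not None:
        pd.DataFrame({"row_id": expr.row_ids, "layer": expr.layers}).to_csv(
            layers_path, sep="\t", index=False
        )


def read_expression(path, layers_path=None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    row_ids = [str(r) for r in df.index]
    if layers_path is not None:
        lay = pd.read_csv(layers_path, sep="\t")
        layer_of = dict(zip(lay["row_id"].astype(str), lay["layer"]))
        layers = [layer_of[r] for r in row_ids]
    else:  # fall back on id prefixes
        layers = ["MR" if r.startswith("MR") else "TF" if r.startswith("TF") else "G" for r in row_ids]
    return ExpressionMatrix(df.to_numpy(dtype=float), row_ids, layers, [str(c) for c in df.columns])


# ----------------------------------------------------------------- benchmarks
def write_benchmark(benchmark, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, (net, expr) in enumerate(benchmark):
        tag = f"grn_{k:03d}"
        write_network(net, out / f"{tag}.edges.tsv", out / f"{tag}.nodes.tsv")
        np.savetxt(out / f"{tag}.hill.tsv", net.hill, fmt="%d")
        write_expression(expr, out / f"{tag}.expr.tsv", out / f"{tag}.layers.tsv")


def read_benchmark(in_dir) -> list[tuple[RegulatoryNetwork, ExpressionMatrix]]:
    out = []
    in_dir = Path(in_dir)
    for edges in sorted(in_dir.glob("grn_*.edges.tsv")):
        tag = edges.name[: -len(".edges.tsv")]
        hill_path = in_dir / f"{tag}.hill.tsv"
        hill = np.loadtxt(hill_path, dtype=np.int64).reshape(-1) if hill_path.exists() else None
        net = read_network(edges, in_dir / f"{tag}.nodes.tsv", hill=hill)
        expr = read_expression(in_dir / f"{tag}.expr.tsv", in_dir / f"{tag}.layers.tsv")
        out.append((net, expr))
    if not out:
        raise ParameterError(f"no benchmark files under {in_dir}")
    return out


# ---------------------------------------------------------------- checkpoints
def save_checkpoint(model, featurization: FeaturizationParams, path) -> None:
    header = {
        "variant": model.variant,
        "n_tf": model.n_tf,
        "eps": featurization.eps,
        "mi_bins": featurization.mi_bins,
        "feature_mask": list(featurization.feature_mask),
    }
    flat = {}
    for k, v in model.state_dict().items():
        if isinstance(v, dict):  # batchnorm running statistics
            for kk, vv in v.items():
                flat[f"bn::{k}::{kk}"] = vv
        else:
            flat[f"p::{k}"] = v
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **flat)


def load_checkpoint(path):
    """Rebuild ``(model, FeaturizationParams)`` from a checkpoint file."""
    data = np.load(path)
    header = json.loads(bytes(data["__header__"]).decode())
    model = (SPNet if header["variant"] == "sp" else MLNet)(header["n_tf"])
    state: dict = {}
    for key in data.files:
        if key.startswith("p::"):
            state[key[3:]] = data[key]
        elif key.startswith("bn::"):
            _, name, stat = key.split("::")
            state.setdefault(name, {})[stat] = data[key]
    model.load_state_dict(state)
    feat = FeaturizationParams(
        eps=float(header["eps"]),
        mi_bins=header["mi_bins"],
        feature_mask=tuple(header["feature_mask"]),
    )
    return model, feat


# --------------------------------------------------------------- predictions
def write_predictions(preds, path) -> None:
    """Ranked 3-column edge list (gene, TF, score), best scores first per gene."""
    rows = []
    for p in preds:
        order = np.argsort(-p.scores)
        rows += [(p.gene, p.tf_ids[i], float(p.scores[i])) for i in order]
    pd.DataFrame(rows, columns=["gene", "TF", "score"]).to_csv(path, sep="\t", index=False)


def write_report(report, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.summary(), fh, indent=2)


# -------------------------------------------------------------------- configs
def load_config(path) -> dict:
    """Parse a YAML/JSON config into parameter objects.

    Recognized blocks: ``topology`` (or a list under ``topologies``),
    ``simulation``, ``featurization``, ``training`` plus free keys
    (``m``, ``n_grn_test`` ...) returned verbatim under ``extra``.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    out: dict = {"extra": {}}
    for key, val in (raw or {}).items():
        if key == "topology":
            out["topology"] = _topology(val)
        elif key == "topologies":
            out["topologies"] = [_topology(v) for v in val]
        elif key == "simulation":
            out["simulation"] = SimulationParams(**val)
        elif key == "featurization":
            if "feature_mask" in val:
                val = {**val, "feature_mask": tuple(val["feature_mask"])}
            out["featurization"] = FeaturizationParams(**val)
        elif key == "training":
            out["training"] = TrainingConfig(**val)
        else:
            out["extra"][key] = val
    return out


def _topology(val: dict) -> TopologyParams:
    if "d_tf_g_range" in val:
        val = {**val, "d_tf_g_range": tuple(val["d_tf_g_range"])}
    return TopologyParams(**val)
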