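"""Readers and writers: TSV tables, edge lists, field configs, scenarios.

All tabular output is tab-separated UTF-8 with LF line endings and canonical
row order, so runs with equal seeds diff empty.  Layer and variable names are
strings throughout the file surface; integer indices never leak into files.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .errors import AlignmentError
from .gibbs import GibbsField, LabelSet, PotentialSet
from .graph import MultilayerGraph, NodeId, canon_key
from .mi import Hypermatrix, MIMatrix, SampleTensor

_ROMAN = (
    "I II III IV V VI VII VIII IX X XI XII XIII XIV XV XVI XVII XVIII XIX XX"
).split()


def default_layer_names(n_layers: int) -> Tuple[str, ...]:
    """Roman-numeral layer names I, II, ... (falling back to L21, L22, ...)."""
    return tuple(
        _ROMAN[h] if h < len(_ROMAN) else f"L{h + 1}" for h in range(n_layers)
    )


def default_var_names(n_vars: int) -> Tuple[str, ...]:
    return tuple(f"V{i + 1}" for i in range(n_vars))


def _names(g_or_dims, var_names, layer_names):
    n_vars, n_layers = g_or_dims
    var_names = tuple(var_names) if var_names else default_var_names(n_vars)
    layer_names = tuple(layer_names) if layer_names else default_layer_names(n_layers)
    if len(var_names) != n_vars or len(layer_names) != n_layers:
        raise ValueError("name registry sizes do not match the grid")
    return var_names, layer_names


# ---------------------------------------------------------------------------
# Graph edge lists


def save_graph_tsv(
    g: MultilayerGraph,
    path,
    var_names: Optional[Sequence[str]] = None,
    layer_names: Optional[Sequence[str]] = None,
) -> None:
    """Edge list TSV: columns var_a layer_a var_b layer_b, canonical order.

    Grid dimensions and name registries ride along in ``#`` header comments so
    isolated vertices survive the round trip.
    """
    var_names, layer_names = _names((g.n_vars, g.n_layers), var_names, layer_names)
    lines = [
        f"# n_vars={g.n_vars}\tn_layers={g.n_layers}",
        "# vars=" + "\t".join(var_names),
        "# layers=" + "\t".join(layer_names),
        "var_a\tlayer_a\tvar_b\tlayer_b",
    ]
    for u, v in sorted(g.edges, key=lambda e: (canon_key(e[0]), canon_key(e[1]))):
        lines.append(
            f"{var_names[u.var]}\t{layer_names[u.layer]}"
            f"\t{var_names[v.var]}\t{layer_names[v.layer]}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_graph_tsv(path) -> Tuple[MultilayerGraph, Tuple[str, ...], Tuple[str, ...]]:
    """Read an edge list written by :func:`save_graph_tsv`.

    Accepts endpoints in either order and deduplicates repeated edges.
    """
    text = Path(path).read_text(encoding="utf-8").splitlines()
    n_vars = n_layers = None
    var_names: Tuple[str, ...] = ()
    layer_names: Tuple[str, ...] = ()
    rows = []
    for line in text:
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("n_vars="):
                parts = dict(p.split("=") for p in body.split("\t"))
                n_vars = int(parts["n_vars"])
                n_layers = int(parts["n_layers"])
            elif body.startswith("vars="):
                var_names = tuple(body[len("vars=") :].split("\t"))
            elif body.startswith("layers="):
                layer_names = tuple(body[len("layers=") :].split("\t"))
            continue
        rows.append(line.split("\t"))
    if n_vars is None or not var_names or not layer_names:
        raise ValueError(f"{path}: missing graph header comments")
    header, *body = rows
    if header != ["var_a", "layer_a", "var_b", "layer_b"]:
        raise ValueError(f"{path}: unexpected edge-list header {header}")
    vidx = {name: i for i, name in enumerate(var_names)}
    lidx = {name: h for h, name in enumerate(layer_names)}
    edges = []
    for va, la, vb, lb in body:
        edges.append(((vidx[va], lidx[la]), (vidx[vb], lidx[lb])))
    g = MultilayerGraph.from_edges(n_vars, n_layers, edges)
    return g, var_names, layer_names


# ---------------------------------------------------------------------------
# Gibbs field configs


def save_field(
    field: GibbsField,
    path,
    var_names: Optional[Sequence[str]] = None,
    layer_names: Optional[Sequence[str]] = None,
) -> None:
    """Field config as a YAML document: grid, labels, per-clique tables."""
    g = field.graph
    var_names, layer_names = _names((g.n_vars, g.n_layers), var_names, layer_names)
    doc = {
        "n_vars": g.n_vars,
        "n_layers": g.n_layers,
        "vars": list(var_names),
        "layers": list(layer_names),
        "labels": [_plain(l) for l in field.labels.labels],
        "default_label": _plain(field.labels.default),
        "edges": [
            [[var_names[u.var], layer_names[u.layer]], [var_names[v.var], layer_names[v.layer]]]
            for u, v in sorted(g.edges, key=lambda e: (canon_key(e[0]), canon_key(e[1])))
        ],
        "potentials": [
            {
                "vertices": [
                    [var_names[v.var], layer_names[v.layer]] for v in subset
                ],
                "table": np.asarray(table).tolist(),
            }
            for subset, table in sorted(
                field.potentials.items(),
                key=lambda kv: (len(kv[0]), [canon_key(v) for v in kv[0]]),
            )
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def _plain(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    return x


def load_field(path) -> Tuple[GibbsField, Tuple[str, ...], Tuple[str, ...]]:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    var_names = tuple(doc["vars"])
    layer_names = tuple(doc["layers"])
    vidx = {name: i for i, name in enumerate(var_names)}
    lidx = {name: h for h, name in enumerate(layer_names)}
    g = MultilayerGraph.from_edges(
        doc["n_vars"],
        doc["n_layers"],
        [((vidx[a[0]], lidx[a[1]]), (vidx[b[0]], lidx[b[1]])) for a, b in doc["edges"]],
    )
    labels = LabelSet(tuple(doc["labels"]), doc["default_label"])
    tables = {
        tuple(NodeId(vidx[v[0]], lidx[v[1]]) for v in pot["vertices"]): np.asarray(
            pot["table"], dtype=float
        )
        for pot in doc["potentials"]
    }
    return GibbsField(g, labels, PotentialSet(tables)), var_names, layer_names


# ---------------------------------------------------------------------------
# Layer sample matrices


def write_layer_matrices(
    data: SampleTensor,
    out_dir,
    var_names: Optional[Sequence[str]] = None,
    layer_names: Optional[Sequence[str]] = None,
    manifest_name: str = "layers.yaml",
) -> Path:
    """One samples x variables TSV per layer plus a manifest mapping name -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    var_names, layer_names = _names((data.n_vars, data.n_layers), var_names, layer_names)
    sample_ids = data.sample_ids or tuple(
        f"S{s + 1}" for s in range(data.n_samples)
    )
    manifest: Dict[str, str] = {}
    for h, lname in enumerate(layer_names):
        fname = f"layer_{lname}.tsv"
        df = pd.DataFrame(
            data.values[:, :, h], index=list(sample_ids), columns=list(var_names)
        )
        df.index.name = "sample_id"
        df.to_csv(out_dir / fname, sep="\t", lineterminator="\n")
        manifest[lname] = fname
    manifest_path = out_dir / manifest_name
    manifest_path.write_text(
        yaml.safe_dump({"layers": manifest}, sort_keys=False), encoding="utf-8"
    )
    return manifest_path


def read_layer_matrices(
    manifest_path,
) -> Tuple[SampleTensor, Tuple[str, ...], Tuple[str, ...]]:
    """Load per-layer TSVs listed in a manifest into a dense SampleTensor.

    All layers must share the same ordered sample-ID column and the same
    ordered variable header; offenders are reported in an AlignmentError.
    Non-numeric cells raise with their row and column.
    """
    manifest_path = Path(manifest_path)
    doc = yaml.safe_load(manifest_path.read_text(encoding="utf-8"))
    layers = doc["layers"] if isinstance(doc, dict) and "layers" in doc else doc
    if not layers:
        raise ValueError(f"{manifest_path}: manifest lists no layers")
    layer_names = tuple(layers.keys())
    frames = []
    for lname in layer_names:
        path = Path(layers[lname])
        if not path.is_absolute():
            path = manifest_path.parent / path
        if not path.exists():
            raise ValueError(f"manifest layer {lname!r}: file not found: {path}")
        df = pd.read_csv(path, sep="\t", index_col=0)
        numeric = df.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & df.notna()
        if bad.to_numpy().any():
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"layer {lname!r}: non-numeric cell at sample "
                f"{df.index[r]!r}, variable {df.columns[c]!r}"
            )
        if numeric.isna().to_numpy().any():
            raise ValueError(f"layer {lname!r}: missing entries are not allowed")
        frames.append((lname, numeric))
    ref_name, ref = frames[0]
    for lname, df in frames[1:]:
        if list(df.index) != list(ref.index):
            off = sorted(set(df.index).symmetric_difference(ref.index)) or ["(order differs)"]
            raise AlignmentError(
                f"layer {lname!r} sample IDs do not match layer {ref_name!r}: "
                f"{off[:10]}"
            )
        if list(df.columns) != list(ref.columns):
            off = sorted(set(df.columns).symmetric_difference(ref.columns)) or ["(order differs)"]
            raise AlignmentError(
                f"layer {lname!r} variable names do not match layer {ref_name!r}: "
                f"{off[:10]}"
            )
    stacked = np.stack([df.to_numpy() for _, df in frames], axis=2)
    if np.all(stacked == np.floor(stacked)):
        stacked = stacked.astype(np.int64)
    var_names = tuple(str(c) for c in ref.columns)
    sample_ids = tuple(str(i) for i in ref.index)
    return (
        SampleTensor(stacked, var_names, layer_names, sample_ids),
        var_names,
        layer_names,
    )


# ---------------------------------------------------------------------------
# Inference outputs


def write_edge_report(
    path,
    mi: MIMatrix,
    adj: Hypermatrix,
    var_names: Optional[Sequence[str]] = None,
    layer_names: Optional[Sequence[str]] = None,
    only_adjacent: bool = True,
) -> None:
    """Weighted edge list: var_a layer_a var_b layer_b mi adjacency."""
    nv, nl = mi.n_vars, mi.n_layers
    var_names, layer_names = _names((nv, nl), var_names, layer_names)
    lines = [
        f"# n_vars={nv}\tn_layers={nl}",
        "# vars=" + "\t".join(var_names),
        "# layers=" + "\t".join(layer_names),
        "var_a\tlayer_a\tvar_b\tlayer_b\tmi\tadjacency",
    ]
    cols = [(i, h) for h in range(nl) for i in range(nv)]
    import itertools as _it

    for (i, h), (j, k) in _it.combinations(cols, 2):
        a = int(adj.values[i, j, h, k])
        if only_adjacent and not a:
            continue
        lines.append(
            f"{var_names[i]}\t{layer_names[h]}\t{var_names[j]}\t{layer_names[k]}"
            f"\t{mi.values[i, j, h, k]:.10g}\t{a}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_edge_report(path) -> Tuple[Hypermatrix, Hypermatrix, Tuple[str, ...], Tuple[str, ...]]:
    """Read an edge report back into (adjacency, strength) hypermatrices."""
    text = Path(path).read_text(encoding="utf-8").splitlines()
    n_vars = n_layers = None
    var_names: Tuple[str, ...] = ()
    layer_names: Tuple[str, ...] = ()
    body = []
    for line in text:
        if not line.strip():
            continue
        if line.startswith("#"):
            s = line[1:].strip()
            if s.startswith("n_vars="):
                parts = dict(p.split("=") for p in s.split("\t"))
                n_vars, n_layers = int(parts["n_vars"]), int(parts["n_layers"])
            elif s.startswith("vars="):
                var_names = tuple(s[5:].split("\t"))
            elif s.startswith("layers="):
                layer_names = tuple(s[7:].split("\t"))
            continue
        body.append(line.split("\t"))
    if n_vars is None or not var_names or not layer_names:
        raise ValueError(f"{path}: missing edge-report header comments")
    header, *rows = body
    vidx = {n: i for i, n in enumerate(var_names)}
    lidx = {n: h for h, n in enumerate(layer_names)}
    a = np.zeros((n_vars, n_vars, n_layers, n_layers))
    w = np.zeros_like(a)
    for va, la, vb, lb, mi_val, adj_val in rows:
        i, h, j, k = vidx[va], lidx[la], vidx[vb], lidx[lb]
        a[i, j, h, k] = a[j, i, k, h] = float(adj_val)
        if int(adj_val):
            w[i, j, h, k] = w[j, i, k, h] = float(mi_val)
    return (
        Hypermatrix(a, weighted=False),
        Hypermatrix(w, weighted=True),
        var_names,
        layer_names,
    )


def write_hypermatrix_coords(path, m: Hypermatrix | MIMatrix) -> None:
    """Sparse 5-column coordinate dump: i j h k value (0-based indices)."""
    lines = ["i\tj\th\tk\tvalue"]
    for i, j, h, k in zip(*np.nonzero(m.values)):
        lines.append(f"{i}\t{j}\t{h}\t{k}\t{m.values[i, j, h, k]:.10g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_centrality_report(
    path,
    adj: Hypermatrix,
    var_names: Optional[Sequence[str]] = None,
    layer_names: Optional[Sequence[str]] = None,
) -> None:
    """Per-variable multidegree plus one k(h,k) column per ordered layer pair."""
    from .tensor import layer_pair_degree, multidegree_centrality

    nv, nl = adj.n_vars, adj.n_layers
    var_names, layer_names = _names((nv, nl), var_names, layer_names)
    k_cols = {
        (h, k): layer_pair_degree(adj, h, k) for h in range(nl) for k in range(nl)
    }
    total = multidegree_centrality(adj)
    header = ["var", "multidegree"] + [
        f"k({layer_names[h]},{layer_names[k]})" for h in range(nl) for k in range(nl)
    ]
    lines = ["\t".join(header)]
    for i in range(nv):
        row = [var_names[i], f"{total[i]:.10g}"] + [
            f"{k_cols[(h, k)][i]:.10g}" for h in range(nl) for k in range(nl)
        ]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Scenario persistence


def save_scenario(scenario, out_dir, var_names=None, layer_names=None) -> Path:
    """Dump a PlantedScenario to a directory (graph, field, samples, manifest)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    g = scenario.graph
    var_names, layer_names = _names((g.n_vars, g.n_layers), var_names, layer_names)
    save_graph_tsv(g, out_dir / "graph.tsv", var_names, layer_names)
    save_field(scenario.field, out_dir / "field.yaml", var_names, layer_names)
    write_layer_matrices(
        scenario.samples, out_dir, var_names, layer_names, manifest_name="layers.yaml"
    )
    manifest = {
        "seed": int(scenario.seed),
        "params": {k: _plain(v) for k, v in scenario.params.items()},
        "graph": "graph.tsv",
        "field": "field.yaml",
        "layers_manifest": "layers.yaml",
    }
    (out_dir / "scenario.yaml").write_text(
        yaml.safe_dump(manifest, sort_keys=False), encoding="utf-8"
    )
    return out_dir / "scenario.yaml"


def load_scenario(scenario_dir):
    """Rebuild a PlantedScenario (joint re-derived from the stored field)."""
    from .gibbs import to_joint_table
    from .synth import PlantedScenario

    scenario_dir = Path(scenario_dir)
    doc = yaml.safe_load((scenario_dir / "scenario.yaml").read_text(encoding="utf-8"))
    graph, var_names, layer_names = load_graph_tsv(scenario_dir / doc["graph"])
    field, _, _ = load_field(scenario_dir / doc["field"])
    samples, _, _ = read_layer_matrices(scenario_dir / doc["layers_manifest"])
    return PlantedScenario(
        graph,
        field,
        to_joint_table(field),
        samples,
        doc["seed"],
        dict(doc.get("params", {})),
    )
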