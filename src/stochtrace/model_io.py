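"""Model and trace I/O: SBML subset, CSV replicas, boxed XML, GraphML.

The boxed XML format couples a reaction model with its compressed simulation
traces in one document.  Replica traces are first resampled onto a shared
uniform grid (zero-order hold), then each per-species value stream is run
through the semantic/gzip/Base64 codec; the document records the grid as
(first time, last time, number of points) plus, per stream, its own
sample count, first/last values and the species' first-appearance time
(tstart).  Documents validate against the XSD shipped with the package.
"""

from __future__ import annotations

import importlib.resources
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lxml import etree

from . import codec
from .align import resample_uniform
from .codec import EncodedStream, IntegrityError
from .model import Reaction, ReactionModel, Species
from .simulate import Trace, TraceSet

__all__ = [
    "FormatError",
    "UnsupportedFeatureError",
    "IntegrityError",
    "read_model_sbml",
    "read_traces_csv",
    "write_traces_csv",
    "box",
    "unbox",
    "boxed_schema",
    "export_graphml",
    "read_graphml",
]

BOXED_NS = "urn:stochtrace:boxed:1"
_B = "{%s}" % BOXED_NS


class FormatError(ValueError):
    """Input file does not conform to the expected format."""


class UnsupportedFeatureError(FormatError):
    """Well-formed input using a construct outside the supported subset."""


# --------------------------------------------------------------------- SBML

_SBML_UNSUPPORTED = (
    "listOfRules",
    "listOfEvents",
    "listOfFunctionDefinitions",
    "listOfConstraints",
    "listOfInitialAssignments",
)


def _local(tag) -> str:
    return etree.QName(tag).localname if isinstance(tag, str) and "}" in tag else str(tag)


def read_model_sbml(path: str | Path) -> ReactionModel:
    """Read a minimal SBML subset: species with initial amounts and
    mass-action reactions whose kinetic law carries a single rate constant.

    Rules, events, function definitions, constraints and initial assignments
    are rejected with an error naming the construct.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as e:
        raise FormatError(f"not an XML file: {e}") from e
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise FormatError(f"root element is {_local(root.tag)!r}, expected 'sbml'")
    for el in root.iter():
        name = _local(el.tag)
        if name in _SBML_UNSUPPORTED:
            raise UnsupportedFeatureError(
                f"SBML construct {name!r} is not supported by this reader"
            )
    model_el = next((el for el in root if _local(el.tag) == "model"), None)
    if model_el is None:
        raise FormatError("SBML file has no model element")

    def children(parent, list_name, item_name):
        lst = next((el for el in parent if _local(el.tag) == list_name), None)
        if lst is None:
            return []
        return [el for el in lst if _local(el.tag) == item_name]

    species = []
    for el in children(model_el, "listOfSpecies", "species"):
        sid = el.get("id")
        if sid is None:
            raise FormatError("species without an id")
        amount = float(el.get("initialAmount", "0"))
        species.append(Species(id=sid, kind="entity", initial_amount=amount))

    reactions = []
    for el in children(model_el, "listOfReactions", "reaction"):
        rid = el.get("id")
        if rid is None:
            raise FormatError("reaction without an id")

        def refs(list_name):
            out = []
            for ref in children(el, list_name, "speciesReference"):
                sid = ref.get("species")
                sto = float(ref.get("stoichiometry", "1"))
                if sto != int(sto) or sto < 1:
                    raise UnsupportedFeatureError(
                        f"non-integer stoichiometry in reaction {rid!r}"
                    )
                out.extend([sid] * int(sto))
            return out

        kin = next((e for e in el if _local(e.tag) == "kineticLaw"), None)
        rate = None
        if kin is not None:
            for sub in kin.iter():
                if _local(sub.tag) in ("parameter", "localParameter"):
                    rate = float(sub.get("value"))
                    break
        if rate is None:
            raise FormatError(
                f"reaction {rid!r} has no kinetic-law rate-constant parameter"
            )
        reactions.append(
            Reaction(
                id=rid,
                reactants=refs("listOfReactants"),
                products=refs("listOfProducts"),
                rate_constant=rate,
                rtype=el.get("name", ""),
            )
        )
    return ReactionModel(
        species=species, reactions=reactions, name=model_el.get("id", "model")
    )


# ---------------------------------------------------------------------- CSV


def read_traces_csv(paths: Sequence[str | Path]) -> TraceSet:
    """Read one replica per CSV file (columns: `time` then one per species;
    '.' decimal separator).  Headers must match across files and times must
    be strictly increasing."""
    if not paths:
        raise ValueError("no trace files given")
    traces = []
    expected: list[str] | None = None
    for p in paths:
        df = pd.read_csv(p, float_precision="round_trip")
        if df.columns[0] != "time":
            raise FormatError(f"{p}: first column must be 'time'")
        cols = list(df.columns[1:])
        if expected is None:
            expected = cols
        elif cols != expected:
            raise FormatError(
                f"{p}: species columns {cols} differ from {expected}"
            )
        times = df["time"].to_numpy(dtype=float)
        if len(times) and (np.diff(times) <= 0).any():
            raise FormatError(f"{p}: times are not strictly increasing")
        traces.append(
            Trace(species=cols, times=times, values=df[cols].to_numpy(dtype=float))
        )
    return TraceSet(traces=traces)


def write_traces_csv(traces: TraceSet, out_dir: str | Path) -> list[Path]:
    """Write one `replica_NNN.csv` per trace (LF newlines, '.' decimals)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, tr in enumerate(traces):
        df = pd.DataFrame({"time": tr.times})
        for k, sp in enumerate(tr.species):
            df[sp] = tr.values[:, k]
        p = out_dir / f"replica_{i:03d}.csv"
        df.to_csv(p, index=False, lineterminator="\n")
        paths.append(p)
    return paths


# ---------------------------------------------------------------- boxed XML


def boxed_schema() -> etree.XMLSchema:
    ref = importlib.resources.files("stochtrace") / "schemas" / "boxed.xsd"
    with importlib.resources.as_file(ref) as p:
        return etree.XMLSchema(etree.parse(str(p)))


def _fmt_float(x: float) -> str:
    return repr(float(x))


def box(
    model: ReactionModel,
    traces: TraceSet,
    n_points: int,
    path: str | Path | None = None,
) -> bytes:
    """Package a model and its replica traces into one boxed XML document.

    Every replica is resampled onto the shared uniform grid (zero-order
    hold), each per-species stream is compressed, and model identification,
    reaction type tags and MIRIAM-style annotations are carried along.
    Returns the serialized document; also writes it when `path` is given.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if not traces.traces:
        raise ValueError("empty trace set")
    t_first = max(tr.t_first for tr in traces)
    t_last = max(tr.t_last for tr in traces)
    if not t_first < t_last:
        raise ValueError("degenerate time span: all traces are single points")

    root = etree.Element(f"{_B}boxedModel", nsmap={None: BOXED_NS}, version="1")
    m_el = etree.SubElement(root, f"{_B}model", name=model.name)
    sp_list = etree.SubElement(m_el, f"{_B}listOfSpecies")
    kinds = {}
    for s in model.species:
        kinds[s.id] = s.kind
        el = etree.SubElement(
            sp_list,
            f"{_B}species",
            id=s.id,
            kind=s.kind,
            initialAmount=_fmt_float(s.initial_amount),
        )
        for key, uri in s.annotations:
            etree.SubElement(el, f"{_B}annotation", dataType=uri, identifier=key)
    r_list = etree.SubElement(m_el, f"{_B}listOfReactions")
    for r in model.reactions:
        el = etree.SubElement(
            r_list,
            f"{_B}reaction",
            id=r.id,
            type=r.rtype,
            rateConstant=_fmt_float(r.rate_constant),
        )
        for tag, ids in (("reactant", r.reactants), ("product", r.products)):
            for sid in sorted(set(ids)):
                etree.SubElement(
                    el,
                    f"{_B}{tag}",
                    species=sid,
                    stoichiometry=str(ids.count(sid)),
                )

    grid_el = etree.SubElement(
        root,
        f"{_B}traceGrid",
        tFirst=_fmt_float(t_first),
        tLast=_fmt_float(t_last),
        nPoints=str(n_points),
    )
    for tr in traces:
        rep_el = etree.SubElement(grid_el, f"{_B}replica")
        if tr.seed is not None:
            rep_el.set("seed", str(tr.seed))
        _, gridded = resample_uniform(tr, t_first, t_last, n_points)
        for k, sid in enumerate(tr.species):
            col = gridded[:, k]
            if kinds.get(sid, "entity") == "variable":
                stream: list = [float(v) for v in col]
                kind = "decimal"
            else:
                stream = [int(v) for v in col]
                kind = "integer"
            enc = codec.compress_stream(stream)
            st_el = etree.SubElement(
                rep_el,
                f"{_B}stream",
                species=sid,
                tstart=_fmt_float(tr.tstart[sid]) if math.isfinite(tr.tstart[sid]) else "INF",
                kind=kind,
                count=str(enc.count),
            )
            if enc.first_value is not None:
                st_el.set("first", _fmt_float(enc.first_value))
                st_el.set("last", _fmt_float(enc.last_value))
            st_el.text = enc.payload
    doc = etree.tostring(
        root, xml_declaration=True, encoding="UTF-8", pretty_print=True
    )
    if path is not None:
        Path(path).write_bytes(doc)
    return doc


def unbox(document: bytes | str | Path) -> tuple[ReactionModel, TraceSet]:
    """Invert :func:`box`: recover the model and the gridded trace set.

    The document is validated against the shipped schema; stream counts
    must match the grid, and corrupt payloads raise an integrity error
    with the offending element path.
    """
    if isinstance(document, (bytes, bytearray)):
        try:
            root = etree.fromstring(bytes(document))
        except etree.XMLSyntaxError as e:
            raise FormatError(f"not an XML document: {e}") from e
    else:
        try:
            root = etree.parse(str(document)).getroot()
        except (OSError, etree.XMLSyntaxError) as e:
            raise FormatError(f"cannot read boxed document: {e}") from e
    schema = boxed_schema()
    if not schema.validate(root):
        err = schema.error_log.last_error
        raise FormatError(f"schema violation at {err.path}: {err.message}")

    m_el = root.find(f"{_B}model")
    species = []
    for el in m_el.find(f"{_B}listOfSpecies"):
        species.append(
            Species(
                id=el.get("id"),
                kind=el.get("kind"),
                initial_amount=float(el.get("initialAmount")),
                annotations=[
                    (a.get("identifier"), a.get("dataType")) for a in el
                ],
            )
        )
    reactions = []
    for el in m_el.find(f"{_B}listOfReactions"):
        reactants: list[str] = []
        products: list[str] = []
        for ref in el:
            target = reactants if _local(ref.tag) == "reactant" else products
            target.extend([ref.get("species")] * int(ref.get("stoichiometry", "1")))
        reactions.append(
            Reaction(
                id=el.get("id"),
                reactants=reactants,
                products=products,
                rate_constant=float(el.get("rateConstant")),
                rtype=el.get("type", ""),
            )
        )
    model = ReactionModel(species=species, reactions=reactions, name=m_el.get("name"))

    grid_el = root.find(f"{_B}traceGrid")
    t_first = float(grid_el.get("tFirst"))
    t_last = float(grid_el.get("tLast"))
    n_points = int(grid_el.get("nPoints"))
    grid = t_first + np.arange(n_points) * ((t_last - t_first) / (n_points - 1))
    grid[-1] = t_last
    traces = []
    for rep_el in grid_el:
        cols = {}
        tstarts = {}
        for st_el in rep_el:
            sid = st_el.get("species")
            count = int(st_el.get("count"))
            if count != n_points:
                raise IntegrityError(
                    f"stream for {sid!r}: count {count} != grid nPoints {n_points}"
                )
            kind = st_el.get("kind")
            first = st_el.get("first")
            last = st_el.get("last")
            conv = int if kind == "integer" else float
            enc = EncodedStream(
                payload=st_el.text or "",
                count=count,
                first_value=conv(float(first)) if first is not None else None,
                last_value=conv(float(last)) if last is not None else None,
                numeric_kind=kind,
            )
            cols[sid] = codec.decompress_stream(enc)
            ts = st_el.get("tstart")
            tstarts[sid] = math.inf if ts == "INF" else float(ts)
        sids = list(cols)
        values = np.column_stack([np.asarray(cols[s], dtype=float) for s in sids])
        seed = rep_el.get("seed")
        traces.append(
            Trace(
                species=sids,
                times=grid.copy(),
                values=values,
                seed=int(seed) if seed is not None else None,
                _tstart=tstarts,
            )
        )
    return model, TraceSet(traces=traces, model_ref=model.name)


# ------------------------------------------------------------------ GraphML

import json

import networkx as nx


def _stringify_graph(graph: nx.Graph) -> nx.Graph:
    g = graph.copy()
    for _, data in g.nodes(data=True):
        if "annotations" in data:
            data["annotations"] = json.dumps(data["annotations"])
    return g


def export_graphml(
    graph: nx.Graph,
    path: str | Path,
    layout=None,
    ranking=None,
    colors=None,
) -> None:
    """Write a reaction graph as GraphML.

    Node attributes carried: kind, annotations (JSON-encoded), and — when
    provided — x/y positions from a layout, centrality scores from a ranking
    and `hsl(h,s,l)` color strings.  Edges keep their reaction id and rtype.
    A write-then-read round trip reproduces nodes, edges and attributes.
    """
    g = _stringify_graph(graph)
    if layout is not None:
        for v, (x, y) in layout.positions.items():
            g.nodes[v]["x"] = float(x)
            g.nodes[v]["y"] = float(y)
    if ranking is not None:
        for v, s in ranking.scores.items():
            g.nodes[v]["centrality"] = float(s)
            g.nodes[v]["rank"] = int(ranking.ranks[v])
    if colors is not None:
        for v, c in colors.items():
            g.nodes[v]["color"] = f"hsl({c.hue:.3f},{c.saturation:.4f},{c.lightness:.4f})"
    nx.write_graphml(g, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    """Read a GraphML file back, decoding JSON-packed annotation lists."""
    g = nx.read_graphml(str(path), force_multigraph=False)
    for _, data in g.nodes(data=True):
        if "annotations" in data:
            data["annotations"] = [tuple(a) for a in json.loads(data["annotations"])]
    return g
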