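"""Declarative network descriptions: parsing, validation, and structural comparison.

A model description is a hierarchical YAML document listing *components*
(nuclei, functional units, actuators) organized into nested named groups,
plus a flat list of typed, delayed *connections* between them.  Flattening
the hierarchy yields a unique dotted path per component
(``brainstem.EWpg``), which is how connections address their endpoints.

Each component parameter carries a *parameter-class* label — fundamental,
empirical, scaling, metaparameter, or weight — recording the epistemic
status of the value (a physical constant, a measured quantity, a unit
choice, a modeling knob, or a free learned parameter).  The labels are
metadata: the simulator does not interpret them, but they keep the
provenance of every number visible in the model file itself.

Structural validation compares the model's directed component graph to a
reference edge list (for instance one derived from connectome data): the
Jaccard index over directed edges, the missing/extra edge diffs, and a
rank correlation of per-node total degree.

Grammar (YAML):

.. code-block:: yaml

    groups:
      brainstem:
        components:
          EWpg: {kind: nucleus, params: {epsilon: {value: 0.1, class: empirical}}}
        groups: {}          # groups nest arbitrarily
    components:             # components may also sit at the top level
      plant:
        kind: actuator
        impl: pupil_plant
        ports: {sphincter: {direction: in}, dilator: {direction: in}}
    connections:
      - {source: brainstem.EWpg, target: plant.sphincter,
         kind: excitatory, weight: 1.0, delay: 1}

Component fields: ``kind`` (nucleus | functional | actuator), ``params``
(name -> {value, class}), ``output_shape`` (``scalar``, ``vector(n)`` or
``matrix(h,w)``), ``impl`` (implementation key for functional/actuator
units), ``external`` (stimulus channels injected by the protocol), and
``ports`` (named non-default endpoints, each with a direction and shape).
Connection fields: ``source``, ``target`` (dotted paths, optionally
suffixed with a declared port), ``kind`` (excitatory | inhibitory |
shunting, or the shorthands E/I/S), ``weight`` (default 1; must be 1
unless ``plastic``), ``delay`` in ticks (integer >= 1), ``taps`` (offsets
for a tapped delay line), and a free-text ``receptor`` annotation carried
as metadata only.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
import yaml
from scipy import stats

from .dynamics import ConnectionKind

__all__ = [
    "ModelSpecError",
    "ParamDecl",
    "ComponentDecl",
    "ConnectionDecl",
    "Group",
    "ModelSpec",
    "Diagnostic",
    "GraphComparison",
    "parse_model_spec",
    "serialize_model_spec",
    "validate_spec",
    "compare_to_reference",
    "read_edge_list",
]

PARAM_CLASSES = ("fundamental", "empirical", "scaling", "metaparameter", "weight")
COMPONENT_KINDS = ("nucleus", "functional", "actuator")

_KIND_ALIASES = {
    "e": ConnectionKind.EXCITATORY,
    "i": ConnectionKind.INHIBITORY,
    "s": ConnectionKind.SHUNTING,
    "excitatory": ConnectionKind.EXCITATORY,
    "inhibitory": ConnectionKind.INHIBITORY,
    "shunting": ConnectionKind.SHUNTING,
}

_SHAPE_RE = re.compile(r"^(scalar|vector\(\d+\)|matrix\(\d+,\s*\d+\))$")
_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


class ModelSpecError(ValueError):
    """Raised for malformed or unresolvable model descriptions."""


def parse_shape(shape: str) -> tuple[int, ...]:
    """Dimensions of an ``output_shape`` string: ``()``, ``(n,)`` or ``(h, w)``."""
    if shape == "scalar":
        return ()
    m = re.match(r"^vector\((\d+)\)$", shape)
    if m:
        return (int(m.group(1)),)
    m = re.match(r"^matrix\((\d+),\s*(\d+)\)$", shape)
    if m:
        return (int(m.group(1)), int(m.group(2)))
    raise ModelSpecError(f"unrecognized shape {shape!r}")


@dataclass(frozen=True)
class ParamDecl:
    """A named real parameter with its parameter-class label."""

    value: float
    param_class: str = "empirical"

    def __post_init__(self) -> None:
        if self.param_class not in PARAM_CLASSES:
            raise ModelSpecError(
                f"unknown parameter class {self.param_class!r}; "
                f"expected one of {PARAM_CLASSES}"
            )


@dataclass(frozen=True)
class PortDecl:
    """A named non-default endpoint on a component."""

    direction: str = "out"  # "in" | "out"
    shape: str = "scalar"

    def __post_init__(self) -> None:
        if self.direction not in ("in", "out"):
            raise ModelSpecError(f"port direction must be in/out, got {self.direction!r}")
        if not _SHAPE_RE.match(self.shape):
            raise ModelSpecError(f"bad port shape {self.shape!r}")


@dataclass
class ComponentDecl:
    """Declaration of one component (nucleus, functional unit, or actuator)."""

    name: str
    kind: str = "nucleus"
    params: dict[str, ParamDecl] = field(default_factory=dict)
    output_shape: str = "scalar"
    impl: str | None = None
    external: tuple[str, ...] = ()
    ports: dict[str, PortDecl] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not _NAME_RE.match(self.name):
            raise ModelSpecError(f"bad component name {self.name!r}")
        if self.kind not in COMPONENT_KINDS:
            raise ModelSpecError(
                f"component {self.name!r}: unknown kind {self.kind!r}"
            )
        if not _SHAPE_RE.match(self.output_shape):
            raise ModelSpecError(
                f"component {self.name!r}: bad output_shape {self.output_shape!r}"
            )


@dataclass
class ConnectionDecl:
    """A typed, delayed, optionally plastic connection between two components."""

    source: str
    target: str
    kind: ConnectionKind = ConnectionKind.EXCITATORY
    weight: float = 1.0
    delay_ticks: int = 1
    plastic: bool = False
    taps: tuple[int, ...] | None = None
    receptor: str | None = None


@dataclass
class Group:
    """A node of the hierarchy: named components plus nested subgroups."""

    name: str
    components: dict[str, ComponentDecl] = field(default_factory=dict)
    subgroups: dict[str, "Group"] = field(default_factory=dict)


@dataclass
class ModelSpec:
    """A parsed model description: a tree of groups plus a connection list."""

    root: Group = field(default_factory=lambda: Group(""))
    connections: list[ConnectionDecl] = field(default_factory=list)

    # -- hierarchy ---------------------------------------------------------
    def components(self) -> dict[str, ComponentDecl]:
        """Flatten the hierarchy into ``dotted.path -> ComponentDecl``."""
        out: dict[str, ComponentDecl] = {}

        def walk(group: Group, prefix: str) -> None:
            for name, comp in group.components.items():
                out[prefix + name] = comp
            for name, sub in group.subgroups.items():
                walk(sub, prefix + name + ".")

        walk(self.root, "")
        return out

    def resolve(self, endpoint: str) -> tuple[str, str | None]:
        """Resolve a connection endpoint to ``(component_path, port_or_None)``.

        The full string is tried as a component path first; failing that,
        the last dotted segment is interpreted as a declared port on the
        prefix component.
        """
        comps = self.components()
        if endpoint in comps:
            return endpoint, None
        if "." in endpoint:
            prefix, port = endpoint.rsplit(".", 1)
            comp = comps.get(prefix)
            if comp is not None and port in comp.ports:
                return prefix, port
        raise ModelSpecError(f"endpoint {endpoint!r} does not resolve to a component")

    def edge_labels(self, aliases: Mapping[str, str] | None = None) -> list[tuple[str, str]]:
        """Directed edges under name normalization (for structural comparison).

        The default label of an endpoint is the component's leaf name, with
        a ``.port`` suffix when a port is addressed; an explicit alias
        table (full endpoint, path, or default label -> reference label)
        overrides it.
        """
        aliases = dict(aliases or {})

        def label(endpoint: str) -> str:
            if endpoint in aliases:
                return aliases[endpoint]
            path, port = self.resolve(endpoint)
            if path in aliases:
                base = aliases[path]
            else:
                base = path.rsplit(".", 1)[-1]
            lab = base + ("." + port if port else "")
            return aliases.get(lab, lab)

        return [(label(c.source), label(c.target)) for c in self.connections]

    # -- (de)serialization -------------------------------------------------
    @classmethod
    def from_dict(cls, doc: Mapping) -> "ModelSpec":
        if doc is None:
            return cls()
        if not isinstance(doc, Mapping):
            raise ModelSpecError("model description must be a mapping at the top level")
        unknown = set(doc) - {"groups", "components", "connections"}
        if unknown:
            raise ModelSpecError(f"unknown top-level keys: {sorted(unknown)}")
        root = _group_from_dict("", doc)
        conns = [_connection_from_dict(i, c) for i, c in enumerate(doc.get("connections") or [])]
        return cls(root=root, connections=conns)

    def to_dict(self) -> dict:
        doc = _group_to_dict(self.root)
        if self.connections:
            doc["connections"] = [_connection_to_dict(c) for c in self.connections]
        return doc


def _component_from_dict(name: str, d: Mapping | None) -> ComponentDecl:
    d = d or {}
    if not isinstance(d, Mapping):
        raise ModelSpecError(f"component {name!r}: declaration must be a mapping")
    unknown = set(d) - {"kind", "params", "output_shape", "impl", "external", "ports"}
    if unknown:
        raise ModelSpecError(f"component {name!r}: unknown fields {sorted(unknown)}")
    params = {}
    for pname, pd in (d.get("params") or {}).items():
        if isinstance(pd, Mapping):
            params[pname] = ParamDecl(
                value=float(pd["value"]), param_class=pd.get("class", "empirical")
            )
        else:
            params[pname] = ParamDecl(value=float(pd))
    ports = {}
    for qname, qd in (d.get("ports") or {}).items():
        qd = qd or {}
        ports[qname] = PortDecl(
            direction=qd.get("direction", "out"), shape=qd.get("shape", "scalar")
        )
    ext = d.get("external") or ()
    if isinstance(ext, str):
        ext = (ext,)
    return ComponentDecl(
        name=name,
        kind=d.get("kind", "nucleus"),
        params=params,
        output_shape=d.get("output_shape", "scalar"),
        impl=d.get("impl"),
        external=tuple(ext),
        ports=ports,
    )


def _component_to_dict(c: ComponentDecl) -> dict:
    d: dict = {}
    if c.kind != "nucleus":
        d["kind"] = c.kind
    if c.params:
        d["params"] = {
            k: {"value": p.value, "class": p.param_class} for k, p in c.params.items()
        }
    if c.output_shape != "scalar":
        d["output_shape"] = c.output_shape
    if c.impl is not None:
        d["impl"] = c.impl
    if c.external:
        d["external"] = list(c.external)
    if c.ports:
        d["ports"] = {
            k: {"direction": p.direction, "shape": p.shape} for k, p in c.ports.items()
        }
    return d


def _group_from_dict(name: str, d: Mapping) -> Group:
    comps = {
        cname: _component_from_dict(cname, cd)
        for cname, cd in (d.get("components") or {}).items()
    }
    subs = {}
    for gname, gd in (d.get("groups") or {}).items():
        if not _NAME_RE.match(gname):
            raise ModelSpecError(f"bad group name {gname!r}")
        gd = gd or {}
        unknown = set(gd) - {"groups", "components"}
        if unknown:
            raise ModelSpecError(f"group {gname!r}: unknown fields {sorted(unknown)}")
        subs[gname] = _group_from_dict(gname, gd)
    return Group(name=name, components=comps, subgroups=subs)


def _group_to_dict(g: Group) -> dict:
    d: dict = {}
    if g.components:
        d["components"] = {k: _component_to_dict(c) for k, c in g.components.items()}
    if g.subgroups:
        d["groups"] = {k: _group_to_dict(s) for k, s in g.subgroups.items()}
    return d


def _connection_from_dict(index: int, d: Mapping) -> ConnectionDecl:
    if not isinstance(d, Mapping):
        raise ModelSpecError(f"connection #{index}: must be a mapping")
    unknown = set(d) - {"source", "target", "kind", "weight", "delay", "plastic", "taps", "receptor"}
    if unknown:
        raise ModelSpecError(f"connection #{index}: unknown fields {sorted(unknown)}")
    try:
        source, target = d["source"], d["target"]
    except KeyError as e:
        raise ModelSpecError(f"connection #{index}: missing field {e.args[0]!r}") from None
    kind_raw = str(d.get("kind", "excitatory")).lower()
    kind = _KIND_ALIASES.get(kind_raw)
    if kind is None:
        raise ModelSpecError(
            f"connection #{index} ({source} -> {target}): unknown kind {kind_raw!r}"
        )
    taps = d.get("taps")
    return ConnectionDecl(
        source=str(source),
        target=str(target),
        kind=kind,
        weight=float(d.get("weight", 1.0)),
        delay_ticks=int(d.get("delay", 1)),
        plastic=bool(d.get("plastic", False)),
        taps=tuple(int(t) for t in taps) if taps else None,
        receptor=d.get("receptor"),
    )


def _connection_to_dict(c: ConnectionDecl) -> dict:
    d: dict = {"source": c.source, "target": c.target, "kind": c.kind.value}
    if c.weight != 1.0:
        d["weight"] = c.weight
    if c.delay_ticks != 1:
        d["delay"] = c.delay_ticks
    if c.plastic:
        d["plastic"] = True
    if c.taps:
        d["taps"] = list(c.taps)
    if c.receptor is not None:
        d["receptor"] = c.receptor
    return d


def parse_model_spec(text: str) -> ModelSpec:
    """Parse a model-description document; round-trips with :func:`serialize_model_spec`."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as e:
        mark = getattr(e, "problem_mark", None)
        where = f" at line {mark.line + 1}, column {mark.column + 1}" if mark else ""
        raise ModelSpecError(f"syntax error{where}: {e}") from e
    return ModelSpec.from_dict(doc)


def serialize_model_spec(spec: ModelSpec) -> str:
    """Serialize a spec back to its on-disk dialect (identity under re-parsing)."""
    return yaml.safe_dump(spec.to_dict(), sort_keys=False, default_flow_style=None)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Diagnostic:
    """One structural problem found by :func:`validate_spec`."""

    code: str
    subject: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.code}] {self.subject}: {self.message}"


def _source_shape(spec: ModelSpec, comp_path: str, port: str | None) -> str:
    comp = spec.components()[comp_path]
    if port is None:
        return comp.output_shape
    return comp.ports[port].shape


def validate_spec(spec: ModelSpec) -> list[Diagnostic]:
    """Structural diagnostics; an empty list means the spec is instantiable.

    Checks: dangling connection endpoints, port directions, delays below one
    tick, bad tap offsets, non-plastic weights differing from 1, non-scalar
    nucleus outputs, non-scalar signals feeding a nucleus, and non-positive
    time constants.
    """
    diags: list[Diagnostic] = []
    comps = spec.components()

    for path, comp in comps.items():
        if comp.kind == "nucleus":
            if comp.output_shape != "scalar":
                diags.append(
                    Diagnostic("nucleus-shape", path, "nucleus outputs must be scalar")
                )
            eps = comp.params.get("epsilon")
            if eps is not None and eps.value <= 0:
                diags.append(
                    Diagnostic("bad-epsilon", path, f"epsilon must be > 0, got {eps.value}")
                )

    for i, conn in enumerate(spec.connections):
        subject = f"connection #{i} ({conn.source} -> {conn.target})"
        endpoints: dict[str, tuple[str, str | None] | None] = {}
        for role, endpoint in (("source", conn.source), ("target", conn.target)):
            try:
                resolved = spec.resolve(endpoint)
            except ModelSpecError:
                diags.append(
                    Diagnostic(
                        "dangling-endpoint",
                        subject,
                        f"{role} {endpoint!r} is not a declared component",
                    )
                )
                resolved = None
            endpoints[role] = resolved
            if resolved is not None and resolved[1] is not None:
                cpath, port = resolved
                want = "out" if role == "source" else "in"
                have = comps[cpath].ports[port].direction
                if have != want:
                    diags.append(
                        Diagnostic(
                            "bad-port",
                            subject,
                            f"{role} port {port!r} on {cpath} has direction "
                            f"{have!r}, expected {want!r}",
                        )
                    )
        if conn.delay_ticks < 1:
            diags.append(
                Diagnostic(
                    "bad-delay",
                    subject,
                    f"delay must be >= 1 tick, got {conn.delay_ticks}",
                )
            )
        if conn.taps is not None and any(t < 1 for t in conn.taps):
            diags.append(Diagnostic("bad-taps", subject, f"tap offsets must be >= 1: {conn.taps}"))
        if not conn.plastic and conn.weight != 1.0:
            diags.append(
                Diagnostic(
                    "nonplastic-weight",
                    subject,
                    f"non-plastic connections must keep weight 1, got {conn.weight}",
                )
            )
        if endpoints["source"] is not None and endpoints["target"] is not None:
            tpath, tport = endpoints["target"]
            if comps[tpath].kind == "nucleus" and tport is None:
                shape = _source_shape(spec, *endpoints["source"])
                if shape != "scalar":
                    diags.append(
                        Diagnostic(
                            "shape-mismatch",
                            subject,
                            f"nucleus {tpath} cannot receive a {shape} signal",
                        )
                    )
    return diags


# ---------------------------------------------------------------------------
# structural comparison
# ---------------------------------------------------------------------------

@dataclass
class GraphComparison:
    """Result of comparing a model's directed edge set to a reference edge list."""

    edge_jaccard: float
    missing_edges: list[tuple[str, str]]
    extra_edges: list[tuple[str, str]]
    degree_agreement: float
    unmapped_nodes: list[str]

    @property
    def identical(self) -> bool:
        return not self.missing_edges and not self.extra_edges


def read_edge_list(source) -> pd.DataFrame:
    """Read a reference edge list (TSV with a header: source, target[, sign])."""
    df = pd.read_csv(source, sep="\t", dtype=str)
    required = {"source", "target"}
    if not required.issubset(df.columns):
        raise ModelSpecError(
            f"reference edge list needs columns {sorted(required)}, got {list(df.columns)}"
        )
    return df


def _as_edge_set(reference) -> set[tuple[str, str]]:
    if isinstance(reference, pd.DataFrame):
        rows: Iterable = reference[["source", "target"]].itertuples(index=False)
        return {(str(s), str(t)) for s, t in rows}
    return {(str(e[0]), str(e[1])) for e in reference}


def compare_to_reference(
    spec: ModelSpec,
    reference,
    aliases: Mapping[str, str] | None = None,
) -> GraphComparison:
    """Directed-edge comparison between a model spec and a reference edge list.

    ``reference`` is a DataFrame from :func:`read_edge_list` or any iterable
    of ``(source, target[, ...])`` rows.  Edges are compared as unweighted
    directed pairs after name normalization (leaf names, optionally
    overridden by an alias table); weights and kinds appear only in the
    diff detail, not in the Jaccard index.  Model nodes that occur in no
    reference edge are reported as unmapped rather than silently dropped.
    Swapping model and reference roles leaves the Jaccard index unchanged.
    """
    model_edges = set(spec.edge_labels(aliases))
    ref_edges = _as_edge_set(reference)

    inter = model_edges & ref_edges
    union = model_edges | ref_edges
    jaccard = len(inter) / len(union) if union else 1.0

    model_nodes = {n for e in model_edges for n in e}
    ref_nodes = {n for e in ref_edges for n in e}
    unmapped = sorted(model_nodes - ref_nodes)

    nodes = sorted(model_nodes | ref_nodes)
    gm = nx.DiGraph(model_edges)
    gr = nx.DiGraph(ref_edges)
    deg_m = [gm.degree(n) if n in gm else 0 for n in nodes]
    deg_r = [gr.degree(n) if n in gr else 0 for n in nodes]
    if len(nodes) < 2:
        degree_agreement = 1.0
    elif deg_m == deg_r:
        # spearman is nan for constant sequences; identical degrees agree fully
        degree_agreement = 1.0
    else:
        import warnings

        with warnings.catch_warnings():
            # constant degree sequences are legitimate inputs; the nan they
            # produce is handled below
            warnings.simplefilter("ignore", stats.ConstantInputWarning)
            rho = stats.spearmanr(deg_m, deg_r).statistic
        degree_agreement = float(rho) if math.isfinite(rho) else 0.0

    return GraphComparison(
        edge_jaccard=jaccard,
        missing_edges=sorted(ref_edges - model_edges),
        extra_edges=sorted(model_edges - ref_edges),
        degree_agreement=degree_agreement,
        unmapped_nodes=unmapped,
    )
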