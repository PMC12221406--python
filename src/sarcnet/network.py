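"""Signed weighted association networks from model summaries.

Every selected (feature, outcome) pair across a stratum of models becomes one
edge whose weight is the averaged standardized coefficient; positive weights
are rendered green and negative red in the optional plot, matching the usual
presentation of such clinical association networks.  Feature node identity
includes the timing tag (COPD tested against 48-hour data is a different node
from COPD tested against preoperative data), so timing-specific clusters stay
distinct.  Outcome measures may themselves appear as predictors, in which
case outcome-to-outcome edges arise naturally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import networkx as nx


@dataclass(frozen=True)
class Stratum:
    """Filter picking the models whose summaries enter one network."""

    name: str = "all"
    variant: Optional[str] = None
    predictor_timepoint: Optional[str] = None
    task: Optional[str] = None

    def matches(self, spec) -> bool:
        if self.variant is not None and spec.variant != self.variant:
            return False
        if (self.predictor_timepoint is not None
                and spec.predictor_timepoint != self.predictor_timepoint):
            return False
        if self.task is not None and spec.task != self.task:
            return False
        return True


#: The two figure-style strata: continuous outcomes against models whose
#: systemic biomarkers were measured preoperatively or within 48 hours.
FIGURE_STRATA = (
    Stratum(name="preop_biomarkers", variant="biomarker_subset",
            predictor_timepoint="preop", task="regression"),
    Stratum(name="h48_biomarkers", variant="biomarker_subset",
            predictor_timepoint="h48", task="regression"),
)


def _feature_node(feature: str, spec) -> str:
    return feature if "@" in feature else f"{feature}@{spec.predictor_timepoint}"


def build_network(models: Sequence, stratum: Stratum = Stratum()) -> nx.DiGraph:
    """Combine selected features and outcomes of a model stratum into a graph.

    ``models`` is a sequence of (spec, summaries, tested_features) triples:
    the model's :class:`~sarcnet.selection.ModelSpec`, its list of
    :class:`~sarcnet.selection.SelectionSummary`, and the feature names that
    survived preprocessing (the "tested" denominator).  When several models
    of the stratum select the same (feature, outcome) pair, the edge weight
    is the unweighted mean of the per-model mean coefficients and the
    encounter count accumulates.
    """
    graph = nx.DiGraph(stratum=stratum.name)
    weights: dict[tuple[str, str], list[float]] = {}
    tested: dict[tuple[str, str], int] = {}
    for spec, summaries, tested_features in models:
        if not stratum.matches(spec):
            continue
        outcome_node = f"{spec.outcome}@{spec.outcome_horizon}"
        for feature in tested_features:
            key = (_feature_node(feature, spec), outcome_node)
            tested[key] = tested.get(key, 0) + 1
        for s in summaries:
            key = (_feature_node(s.feature, spec), outcome_node)
            weights.setdefault(key, []).append(s.mean_coefficient)
    for (src, dst) in sorted(weights):
        vals = weights[(src, dst)]
        w = sum(vals) / len(vals)
        if w == 0.0:
            continue
        graph.add_node(src, type="feature")
        graph.add_node(dst, type="outcome")
        graph.add_edge(src, dst, weight=float(w),
                       sign=1 if w > 0 else -1,
                       encounter_count=len(vals),
                       models_tested=tested.get((src, dst), len(vals)))
    return graph


def export_network(graph: nx.DiGraph, path, fmt: str = "graphml") -> None:
    """Write a network as GraphML or a TSV edge list."""
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\tsign\tencounter_count\tmodels_tested\n")
            for src, dst, d in sorted(graph.edges(data=True)):
                fh.write(f"{src}\t{dst}\t{d['weight']!r}\t{d['sign']}"
                         f"\t{d['encounter_count']}\t{d['models_tested']}\n")
    else:
        raise ValueError(f"unknown network format {fmt!r}; use 'graphml' or 'tsv'")


def read_network(path, fmt: str = "graphml") -> nx.DiGraph:
    """Read a network written by :func:`export_network`."""
    if fmt == "graphml":
        g = nx.read_graphml(path)
        out = nx.DiGraph(**g.graph)
        for node, d in g.nodes(data=True):
            out.add_node(node, **d)
        for src, dst, d in g.edges(data=True):
            out.add_edge(src, dst, weight=float(d["weight"]), sign=int(d["sign"]),
                         encounter_count=int(d["encounter_count"]),
                         models_tested=int(d["models_tested"]))
        return out
    if fmt == "tsv":
        out = nx.DiGraph()
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for line in fh:
                row = dict(zip(header, line.rstrip("\n").split("\t")))
                out.add_node(row["source"], type="feature")
                out.add_node(row["target"], type="outcome")
                out.add_edge(row["source"], row["target"],
                             weight=float(row["weight"]), sign=int(row["sign"]),
                             encounter_count=int(row["encounter_count"]),
                             models_tested=int(row["models_tested"]))
        return out
    raise ValueError(f"unknown network format {fmt!r}")


def plot_network(graph: nx.DiGraph, path, seed: int = 0) -> None:
    """Quick-look spring-layout plot; green positive, red negative edges."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 7))
    pos = nx.spring_layout(graph, seed=seed)
    colors = ["green" if d["sign"] > 0 else "red"
              for _, _, d in graph.edges(data=True)]
    widths = [1.0 + 4.0 * abs(d["weight"]) for _, _, d in graph.edges(data=True)]
    node_colors = ["#f4a261" if d.get("type") == "outcome" else "#a8dadc"
                   for _, d in graph.nodes(data=True)]
    nx.draw_networkx(graph, pos=pos, ax=ax, edge_color=colors, width=widths,
                     node_color=node_colors, font_size=7, node_size=450)
    ax.set_axis_off()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
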