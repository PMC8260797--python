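"""Interspecific olfactory communication network.

Nodes are species; a directed edge detector → producer (labeled by the
trichoid sensillum class, at1 or at4) exists when some male-specific
compound of the producer elicits a mean single-sensillum response strictly
above the exclusion threshold (default 10 spikes/s — responses at or below
it are excluded) in the detector.  Self-loops record a species detecting
its own conspecific male compounds.

The olfactory clustering coefficient of a focal species and sensillum is
the number of *other* species it detects divided by the number of all
other species in the panel, hence a value in [0, 1] (0: no species
detected; 1: all detected).  Self-loops enter neither numerator nor
denominator.
"""

from __future__ import annotations

import warnings

import networkx as nx
import pandas as pd

from .chemoprofile import CompoundCatalog
from .phylosignal import StatResult, rank_sum_test

SENSILLA = ("at1", "at4")
RESPONSE_THRESHOLD = 10.0  # spikes/s; responses <= threshold are excluded

__all__ = [
    "DetectionNetwork",
    "build_network",
    "clustering_coefficient",
    "self_loop_summary",
    "compare_coefficients",
]


class DetectionNetwork:
    """Directed detection graph with per-sensillum edges and self-loops."""

    def __init__(self, species):
        self.graph = nx.MultiDiGraph()
        self.graph.add_nodes_from(species)

    @property
    def species(self) -> list:
        return sorted(self.graph.nodes)

    def add_detection(self, detector, producer, sensillum, compound):
        if sensillum not in SENSILLA:
            raise ValueError(f"unknown sensillum {sensillum!r}")
        if self.graph.has_edge(detector, producer, key=sensillum):
            self.graph[detector][producer][sensillum]["compounds"].add(compound)
        else:
            self.graph.add_edge(
                detector, producer, key=sensillum, sensillum=sensillum,
                compounds={compound},
            )

    def detected_species(self, detector, sensillum) -> set:
        """Other species whose compounds `detector` detects via `sensillum`."""
        if detector not in self.graph:
            raise KeyError(f"unknown species {detector!r}")
        return {
            producer
            for _, producer, key in self.graph.out_edges(detector, keys=True)
            if key == sensillum and producer != detector
        }

    def has_self_loop(self, species, sensillum) -> bool:
        return self.graph.has_edge(species, species, key=sensillum)

    def edge_list(self) -> pd.DataFrame:
        rows = [
            (u, v, k, ";".join(sorted(map(str, d["compounds"]))))
            for u, v, k, d in self.graph.edges(keys=True, data=True)
        ]
        return pd.DataFrame(
            rows, columns=["detector", "producer", "sensillum", "compounds"]
        )


def build_network(
    catalog: CompoundCatalog,
    rm: pd.DataFrame,
    threshold: float = RESPONSE_THRESHOLD,
) -> DetectionNetwork:
    """Build the detection network from calls and a response matrix.

    `rm` needs columns detector, compound, sensillum, mean_response (and
    optionally n).  Only male-specific compounds create edges; responses
    must be strictly greater than `threshold` (inhibitory/negative
    responses never create edges).  Compounds absent from the catalog are
    ignored with a warning.  Monomorphic species are nodes (they can
    detect) but are never detected.
    """
    required = {"detector", "compound", "sensillum", "mean_response"}
    missing = required - set(rm.columns)
    if missing:
        raise ValueError(f"response matrix missing columns: {sorted(missing)}")
    species = set(rm["detector"])
    species.update(catalog.dimorphic_species)
    species.update(catalog.monomorphic_species)
    for producers in catalog.producing_species.values():
        species.update(producers)
    net = DetectionNetwork(sorted(species))

    male = set(catalog.male_specific)
    unknown = set(rm["compound"]) - set(catalog.specificity.index)
    if unknown:
        warnings.warn(
            f"{len(unknown)} response-matrix compounds absent from catalog; "
            "ignored", stacklevel=2,
        )
    hits = rm[rm["mean_response"] > threshold]
    for row in hits.itertuples(index=False):
        if row.compound not in male:
            continue
        for producer in catalog.producing_species.get(row.compound, ()):
            net.add_detection(row.detector, producer, row.sensillum,
                              row.compound)
    return net


def clustering_coefficient(net: DetectionNetwork, focal, sensillum) -> float:
    """Fraction of other panel species detected by `focal` via `sensillum`."""
    n = len(net.graph.nodes)
    if n < 2:
        raise ValueError("network needs >= 2 species")
    detected = net.detected_species(focal, sensillum)
    return len(detected) / (n - 1)


def coefficient_table(net: DetectionNetwork) -> pd.DataFrame:
    """Per-species clustering coefficients for both sensilla."""
    rows = [
        (s, clustering_coefficient(net, s, "at1"),
         clustering_coefficient(net, s, "at4"))
        for s in net.species
    ]
    return pd.DataFrame(rows, columns=["species", "at1", "at4"]).set_index(
        "species"
    )


def self_loop_summary(net: DetectionNetwork) -> pd.DataFrame:
    """Per-species, per-sensillum self-loop flags (conspecific detection).

    The returned frame has boolean at1/at4 columns; totals per sensillum
    are in ``.attrs["totals"]``.
    """
    rows = [
        (s, net.has_self_loop(s, "at1"), net.has_self_loop(s, "at4"))
        for s in net.species
    ]
    out = pd.DataFrame(rows, columns=["species", "at1", "at4"]).set_index(
        "species"
    )
    out.attrs["totals"] = {
        "at1": int(out["at1"].sum()), "at4": int(out["at4"].sum())
    }
    return out


def compare_coefficients(net: DetectionNetwork) -> StatResult:
    """at1-vs-at4 clustering-coefficient comparison (two-sided
    Mann-Whitney U over species, unpaired)."""
    tab = coefficient_table(net)
    if len(tab) < 2:
        raise ValueError("need >= 2 species to compare sensilla")
    return rank_sum_test(tab["at1"].values, tab["at4"].values)
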