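"""Resting-state network connectivity measures and morphometry ingestion.

Connectivity is summarized per subject by two statistics over a 6-network
atlas (language LAN, default-mode DMN, executive-control ECN, salience SAL,
sensorimotor SMN, auditory AN):

* cohesiveness — the mean Fisher-z Pearson correlation over all within-network
  node pairs;
* integration — the Fisher-z correlation between the average time series of
  the hub network (LAN by default) and each other network.

With 6 networks and hub-centric integration this yields 11 measures per
subject (6 cohesiveness + 5 integration); an all-pairs integration option
gives the full 15 pairs. Correlations are clipped to 1 − 1e−7 in magnitude
before atanh so duplicated series stay finite.

Morphometry arrives as a TSV of 68 Desikan–Killiany cortical thickness values
(mm) and 20 subcortical volumes (mm³) per subject, validated against a named
schema.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (AlignmentError, AtlasError, DomainError, NonPositiveValue,
                     SchemaViolation, ZeroVarianceMean, ZeroVarianceNode)
from .matrix import FeatureMatrix

NETWORK_NAMES = ("LAN", "DMN", "ECN", "SAL", "SMN", "AN")

R_CLIP_EPS = 1e-7


# --------------------------------------------------------------------------- #
# atlas and time-series containers
# --------------------------------------------------------------------------- #

@dataclass
class NetworkAtlas:
    """Named node groupings with a designated hub network."""
    networks: dict[str, frozenset]
    hub_network: str = "LAN"

    def __post_init__(self) -> None:
        self.networks = {k: frozenset(v) for k, v in self.networks.items()}
        if len(self.networks) < 2:
            raise AtlasError("atlas needs at least 2 networks")
        if self.hub_network not in self.networks:
            raise AtlasError(f"hub network {self.hub_network!r} not in atlas")
        seen: set = set()
        for name, nodes in self.networks.items():
            if len(nodes) < 2:
                raise AtlasError(f"network {name!r} has fewer than 2 nodes")
            if seen & nodes:
                raise AtlasError(f"network {name!r} overlaps another network")
            seen |= nodes

    @property
    def names(self) -> list[str]:
        return list(self.networks)

    @property
    def all_nodes(self) -> frozenset:
        return frozenset().union(*self.networks.values())

    @classmethod
    def from_json(cls, path) -> "NetworkAtlas":
        spec = json.loads(Path(path).read_text(encoding="utf-8"))
        hub = spec.pop("hub", "LAN")
        return cls(networks={k: frozenset(v) for k, v in spec.items()}, hub_network=hub)

    def to_json(self, path) -> None:
        payload: dict = {k: sorted(v) for k, v in self.networks.items()}
        payload["hub"] = self.hub_network
        Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


@dataclass
class TimeSeriesPanel:
    """Per-subject node → time-series mapping (all series share length T ≥ 8)."""
    subject_id: str
    series: dict[str, np.ndarray]
    T: int = field(init=False)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.series.values()}
        if len(lengths) != 1:
            raise ValueError(f"subject {self.subject_id!r}: unequal series lengths")
        self.T = lengths.pop()
        if self.T < 8:
            raise ValueError(f"subject {self.subject_id!r}: T = {self.T} < 8")
        self.series = {k: np.asarray(v, dtype=float) for k, v in self.series.items()}
        for node, v in self.series.items():
            if not np.all(np.isfinite(v)):
                raise ValueError(f"subject {self.subject_id!r}: non-finite values at node {node!r}")

    def stack(self, nodes) -> np.ndarray:
        missing = [n for n in nodes if n not in self.series]
        if missing:
            raise AlignmentError(f"subject {self.subject_id!r}: missing nodes {missing}")
        return np.vstack([self.series[n] for n in nodes])

    def to_tsv(self, path) -> None:
        df = pd.DataFrame({n: s for n, s in self.series.items()}).T
        df.index.name = "node"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, subject_id: str | None = None) -> "TimeSeriesPanel":
        df = pd.read_csv(path, sep="\t", index_col="node")
        sid = subject_id if subject_id is not None else Path(path).stem
        return cls(subject_id=sid,
                   series={str(n): df.loc[n].to_numpy(dtype=float) for n in df.index})


# --------------------------------------------------------------------------- #
# connectivity statistics
# --------------------------------------------------------------------------- #

def fisher_z(r: float) -> float:
    """Variance-stabilizing atanh of a correlation, clipped near ±1.

    Raises
    ------
    DomainError
        If |r| exceeds 1 beyond numerical tolerance.
    """
    if abs(r) > 1 + 1e-12:
        raise DomainError(f"|r| = {abs(r)} > 1")
    return math.atanh(float(np.clip(r, -1 + R_CLIP_EPS, 1 - R_CLIP_EPS)))


def _check_variance(data: np.ndarray, nodes, subject: str) -> None:
    sds = data.std(axis=1)
    for node, sd in zip(nodes, sds):
        if sd == 0:
            raise ZeroVarianceNode(f"subject {subject!r}: node {node!r} is constant")


def network_cohesiveness(p: TimeSeriesPanel, nodes) -> float:
    """Mean Fisher-z correlation over all unordered within-network node pairs."""
    nodes = sorted(nodes)
    if len(nodes) < 2:
        raise AtlasError("cohesiveness needs at least 2 nodes")
    data = p.stack(nodes)
    _check_variance(data, nodes, p.subject_id)
    r = np.corrcoef(data)
    iu = np.triu_indices(len(nodes), k=1)
    return float(np.mean([fisher_z(v) for v in r[iu]]))


def network_integration(p: TimeSeriesPanel, nodes_a, nodes_b) -> float:
    """Fisher-z correlation between the two networks' average time series."""
    nodes_a, nodes_b = sorted(nodes_a), sorted(nodes_b)
    if set(nodes_a) & set(nodes_b):
        raise AtlasError("integration needs disjoint node sets")
    if len(nodes_a) < 2 or len(nodes_b) < 2:
        raise AtlasError("integration needs >= 2 nodes per network")
    a = p.stack(nodes_a)
    b = p.stack(nodes_b)
    _check_variance(a, nodes_a, p.subject_id)
    _check_variance(b, nodes_b, p.subject_id)
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    if mean_a.std() == 0 or mean_b.std() == 0:
        raise ZeroVarianceMean(f"subject {p.subject_id!r}: degenerate network mean series")
    r = float(np.corrcoef(mean_a, mean_b)[0, 1])
    return fisher_z(r)


def connectivity_measure_names(atlas: NetworkAtlas, all_pairs: bool = False) -> list[str]:
    names = [f"coh_{net}" for net in atlas.names]
    if all_pairs:
        nets = atlas.names
        names += [f"int_{a}_{b}" for i, a in enumerate(nets) for b in nets[i + 1:]]
    else:
        hub = atlas.hub_network
        names += [f"int_{hub}_{net}" for net in atlas.names if net != hub]
    return names


def connectivity_vector(p: TimeSeriesPanel, atlas: NetworkAtlas,
                        all_pairs: bool = False) -> dict[str, float]:
    """All connectivity measures for one subject, keyed by stable names.

    Hub-centric (default): cohesiveness of every network plus integration of
    the hub with each other network — 11 measures for a 6-network atlas.
    """
    out: dict[str, float] = {}
    for net, nodes in atlas.networks.items():
        out[f"coh_{net}"] = network_cohesiveness(p, nodes)
    if all_pairs:
        nets = atlas.names
        for i, a in enumerate(nets):
            for b in nets[i + 1:]:
                out[f"int_{a}_{b}"] = network_integration(
                    p, atlas.networks[a], atlas.networks[b])
    else:
        hub = atlas.hub_network
        for net in atlas.names:
            if net != hub:
                out[f"int_{hub}_{net}"] = network_integration(
                    p, atlas.networks[hub], atlas.networks[net])
    return out


# --------------------------------------------------------------------------- #
# morphometry
# --------------------------------------------------------------------------- #

#: Desikan–Killiany cortical parcellation, 34 regions per hemisphere.
DESIKAN_KILLIANY_REGIONS = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal", "middletemporal",
    "paracentral", "parahippocampal", "parsopercularis", "parsorbitalis",
    "parstriangularis", "pericalcarine", "postcentral", "posteriorcingulate",
    "precentral", "precuneus", "rostralanteriorcingulate",
    "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
    "superiortemporal", "supramarginal", "temporalpole", "transversetemporal",
)

#: Bilateral subcortical structures, 10 per hemisphere.
SUBCORTICAL_STRUCTURES = (
    "Thalamus-Proper", "Caudate", "Putamen", "Pallidum", "Hippocampus",
    "Amygdala", "Accumbens-area", "VentralDC", "Lateral-Ventricle",
    "Cerebellum-Cortex",
)


def default_morphometry_schema() -> dict[str, str]:
    """Feature name → role ('cortical_thickness' | 'subcortical_volume').

    68 thickness features (34 regions × 2 hemispheres) and 20 volumes.
    """
    schema: dict[str, str] = {}
    for hemi in ("lh", "rh"):
        for region in DESIKAN_KILLIANY_REGIONS:
            schema[f"{hemi}_{region}_thickness"] = "cortical_thickness"
    for side in ("Left", "Right"):
        for s in SUBCORTICAL_STRUCTURES:
            schema[f"{side}-{s}"] = "subcortical_volume"
    return schema


def read_morphometry_table(path, schema: dict[str, str] | None = None,
                           impute_missing: bool = False) -> FeatureMatrix:
    """Load and validate a subjects × morphometry TSV.

    Raises
    ------
    SchemaViolation
        Feature names absent/unknown, or role counts wrong (default 68 + 20).
    NonPositiveValue
        A thickness or volume ≤ 0 (named subject and feature).
    """
    schema = schema if schema is not None else default_morphometry_schema()
    df = pd.read_csv(path, sep="\t", index_col="subject_id")
    df.index = df.index.astype(str)
    missing = sorted(set(schema) - set(df.columns))
    unknown = sorted(set(df.columns) - set(schema))
    if missing or unknown:
        raise SchemaViolation(f"missing features: {missing}; unknown features: {unknown}")
    df = df[list(schema)]
    if df.isna().any().any():
        if not impute_missing:
            raise SchemaViolation("missing values present (pass impute_missing=True to mean-impute)")
        df = df.fillna(df.mean())
    bad = np.argwhere(df.to_numpy() <= 0)
    if bad.size:
        i, j = bad[0]
        raise NonPositiveValue(
            f"subject {df.index[i]!r}, feature {df.columns[j]!r}: value {df.iat[i, j]}")
    roles = pd.Series(schema)
    n_thick = int((roles == "cortical_thickness").sum())
    n_vol = int((roles == "subcortical_volume").sum())
    return FeatureMatrix(df, provenance="morphometry", state="raw",
                         meta={"n_cortical_thickness": n_thick, "n_subcortical_volume": n_vol})


def assemble_connectivity_matrix(vectors: dict[str, dict[str, float]],
                                 atlas: NetworkAtlas,
                                 all_pairs: bool = False) -> FeatureMatrix:
    """Stack per-subject connectivity dicts; columns in the documented order."""
    names = connectivity_measure_names(atlas, all_pairs=all_pairs)
    rows = {}
    for sid, vec in vectors.items():
        if set(vec) != set(names):
            raise AlignmentError(f"subject {sid!r}: measure names do not match atlas")
        rows[sid] = [vec[n] for n in names]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    return FeatureMatrix(df, provenance="connectivity", state="raw")
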