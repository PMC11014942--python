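"""Nitrogen-cycle marker-gene inventories.

Maps gene-level annotation counts (qPCR copies per ng DNA, relative
abundance, or presence counts from genomes) onto nitrogen-cycle processes
and produces a process x sample potential matrix plus absence calls.
The default panel covers: N2 fixation (nifH), nitrification (amoA, hao,
nxrB), denitrification (napA, narG, nirS, nirK, norB, nosZ), DNRA (nrfA),
assimilatory nitrite reduction (nasA, nirA), and anammox (hzo, hzs).
An optional energy/carbon panel screens respiration, trace-gas and
carbon-fixation markers (coxL, uptake [NiFe]-hydrogenase, CBB, 3-HP).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, EmptyInventoryError, SchemaError

__all__ = [
    "GeneProcessMap",
    "AnnotationTable",
    "NCycleInventory",
    "NCYCLE_PANEL",
    "ENERGY_PANEL",
    "GENE_ALIASES",
    "QPCR_PRESENCE_THRESHOLD",
    "build_inventory",
    "compare_groups",
    "screen_markers",
]

# Explicit alias table for symbol normalization. Matching is
# case-insensitive; suffixes are never stripped by fuzzy rules (amoA and
# amoB are different genes).
GENE_ALIASES: dict[str, str] = {
    "nirs/k": "nirS",  # shorthand sometimes used for the nir pair
    "nar": "narG",
    "nap": "napA",
    "nor": "norB",
    "nos": "nosZ",
}

# qPCR-mode presence threshold: ~10 copies per ng DNA is the yardstick
# below which a marker is treated as background.
QPCR_PRESENCE_THRESHOLD = 10.0

_DEFAULT_NCYCLE: dict[str, tuple[str, ...]] = {
    "n2_fixation": ("nifH",),
    "nitrification": ("amoA", "hao", "nxrB"),
    "denitrification": ("napA", "narG", "nirS", "nirK", "norB", "nosZ"),
    "dnra": ("nrfA",),
    "anr": ("nasA", "nirA"),
    "anammox": ("hzo", "hzs"),
}

_DEFAULT_ENERGY: dict[str, tuple[str, ...]] = {
    "aerobic_respiration": ("coxA", "ccoN", "cydA"),
    "co_oxidation": ("coxL",),
    "h2_oxidation": ("hyd_NiFe_1h", "hyd_NiFe_1l", "hyd_NiFe_2a"),
    "cbb_fixation": ("rbcL",),
    "hp_3_fixation": ("accC", "pccB"),
}


def _norm_symbol(symbol: str) -> str:
    key = symbol.strip()
    low = key.lower()
    return GENE_ALIASES.get(low, key)


@dataclass(frozen=True)
class GeneProcessMap:
    """Mapping from processes to their marker-gene sets.

    ``rule`` per process: "any" (default; one detected marker evidences the
    process) or "all". A gene may belong to several processes and then
    contributes to each.
    """

    processes: dict[str, frozenset[str]]
    rules: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        # an empty panel is legal (screening yields an empty matrix)
        norm = {
            p: frozenset(_norm_symbol(g) for g in genes)
            for p, genes in self.processes.items()
        }
        for p, genes in norm.items():
            if not genes:
                raise ConfigurationError(f"process {p!r} maps to no genes")
        object.__setattr__(self, "processes", norm)
        for p, r in self.rules.items():
            if r not in ("any", "all"):
                raise ConfigurationError(f"rule for {p!r} must be any/all, got {r!r}")

    def rule(self, process: str) -> str:
        return self.rules.get(process, "any")

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for g in self.processes.values():
            out |= g
        return frozenset(out)

    def lookup(self, symbol: str) -> list[str]:
        """Processes a gene symbol belongs to (case-insensitive)."""
        s = _norm_symbol(symbol).lower()
        return [p for p, genes in self.processes.items()
                if s in {g.lower() for g in genes}]


NCYCLE_PANEL = GeneProcessMap(
    {p: frozenset(g) for p, g in _DEFAULT_NCYCLE.items()}
)
ENERGY_PANEL = GeneProcessMap(
    {p: frozenset(g) for p, g in _DEFAULT_ENERGY.items()}
)


@dataclass(frozen=True)
class AnnotationTable:
    """Samples/genomes x gene-symbol abundance matrix.

    ``value_kind`` tags the unit: "copies_per_ng", "relative", or
    "presence". Values must be non-negative. Columns that resolve to no
    panel process are retained and listed in ``unmapped`` by the inventory
    builder, never dropped silently.
    """

    data: pd.DataFrame
    value_kind: str = "copies_per_ng"

    def __post_init__(self) -> None:
        if self.value_kind not in ("copies_per_ng", "relative", "presence"):
            raise ConfigurationError(f"unknown value_kind {self.value_kind!r}")
        df = self.data
        if df.empty and df.columns.empty:
            raise SchemaError("annotation table has no gene columns")
        vals = df.to_numpy(dtype=float)
        if vals.size and (np.isnan(vals).any() or (vals < 0).any()):
            raise SchemaError("annotation values must be non-negative and finite")
        object.__setattr__(self, "data", df.astype(float))


@dataclass(frozen=True)
class NCycleInventory:
    """Aggregated process potential per sample plus absence calls.

    ``abundance`` and ``presence`` are process x sample frames;
    ``absent_per_sample`` maps sample -> processes absent there;
    ``absent_global`` lists processes absent in every sample.
    """

    abundance: pd.DataFrame
    presence: pd.DataFrame
    absent_per_sample: dict[str, list[str]]
    absent_global: list[str]
    threshold: float
    agg: str
    unmapped: list[str] = field(default_factory=list)


def build_inventory(
    table: AnnotationTable,
    gmap: GeneProcessMap = NCYCLE_PANEL,
    agg: str = "sum",
    threshold: float = 0.0,
) -> NCycleInventory:
    """Aggregate gene abundances into process potentials.

    Process abundance per sample is the ``sum`` (default) or ``max`` over
    that process's genes present in the table; a gene mapped to several
    processes contributes to each. Presence is abundance > ``threshold``
    (default 0: any positive signal counts as potential). A process whose
    panel genes are all missing from the table scores 0.
    """
    if agg not in ("sum", "max"):
        raise ConfigurationError(f"agg must be sum/max, got {agg!r}")
    if threshold < 0:
        raise ConfigurationError(f"threshold must be >= 0, got {threshold}")
    df = table.data
    colmap: dict[str, list[str]] = {}
    unmapped: list[str] = []
    for col in df.columns:
        procs = gmap.lookup(str(col))
        if procs:
            colmap[col] = procs
        else:
            unmapped.append(str(col))
    if not colmap:
        raise EmptyInventoryError(
            "no annotation column maps to any process in the panel"
        )
    samples = list(df.index.astype(str))
    processes = list(gmap.processes)
    abundance = pd.DataFrame(0.0, index=processes, columns=samples)
    for proc in processes:
        cols = [c for c, ps in colmap.items() if proc in ps]
        if not cols:
            continue
        block = df[cols].T.to_numpy(dtype=float)  # genes x samples
        vec = block.sum(axis=0) if agg == "sum" else block.max(axis=0)
        abundance.loc[proc] = vec
    presence = abundance > threshold
    absent_per_sample = {
        s: [p for p in processes if not presence.at[p, s]] for s in samples
    }
    absent_global = [p for p in processes if not presence.loc[p].any()]
    return NCycleInventory(
        abundance=abundance,
        presence=presence,
        absent_per_sample=absent_per_sample,
        absent_global=absent_global,
        threshold=float(threshold),
        agg=agg,
        unmapped=unmapped,
    )


def compare_groups(inv_a: NCycleInventory, inv_b: NCycleInventory) -> pd.DataFrame:
    """Per-process contrast of two inventories (e.g. soils vs sediments).

    Returns mean aggregated abundance per side, their difference, and the
    presence concordance (fraction of processes-present agreement across
    the pooled sample sets, computed per process on the any-sample level).
    """
    pa, pb = set(inv_a.abundance.index), set(inv_b.abundance.index)
    if pa != pb:
        raise SchemaError(
            f"process sets differ: only-left={sorted(pa - pb)}, "
            f"only-right={sorted(pb - pa)}"
        )
    processes = list(inv_a.abundance.index)
    rows = []
    for p in processes:
        mean_a = float(inv_a.abundance.loc[p].mean())
        mean_b = float(inv_b.abundance.loc[p].mean())
        present_a = bool(inv_a.presence.loc[p].any())
        present_b = bool(inv_b.presence.loc[p].any())
        rows.append(
            {
                "process": p,
                "mean_abundance_a": mean_a,
                "mean_abundance_b": mean_b,
                "difference": mean_a - mean_b,
                "present_a": present_a,
                "present_b": present_b,
                "concordant": present_a == present_b,
            }
        )
    return pd.DataFrame(rows).set_index("process")


def screen_markers(
    table: AnnotationTable,
    panel: GeneProcessMap = ENERGY_PANEL,
    threshold: float = 0.0,
) -> pd.DataFrame:
    """Boolean presence of each panel feature per row (genome or sample).

    A feature with rule "any" is present when any of its markers exceeds
    the threshold; rule "all" requires every marker. Suited to
    presence/absence heatmap-style screening of genome sets.
    """
    if not panel.processes:
        return pd.DataFrame(index=table.data.index.astype(str))
    df = table.data
    lowcols = {str(c).lower(): c for c in df.columns}
    out: dict[str, pd.Series] = {}
    for feature, genes in panel.processes.items():
        cols = [lowcols[g.lower()] for g in genes if g.lower() in lowcols]
        if not cols or (panel.rule(feature) == "all" and len(cols) < len(genes)):
            # a marker absent from the table cannot satisfy an "all" rule
            out[feature] = pd.Series(False, index=df.index)
            continue
        hits = df[cols] > threshold
        out[feature] = hits.all(axis=1) if panel.rule(feature) == "all" else hits.any(axis=1)
    result = pd.DataFrame(out)
    result.index = result.index.astype(str)
    return result
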