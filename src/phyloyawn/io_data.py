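"""Reading, validation, filtering and aggregation of yawn-event and
species-trait tables, and alignment of the species table to a phylogeny.

The analysis-ready unit is a species-level table: mean yawn duration per
species (computed from per-yawn events), log-transformed body/brain mass
and neuron counts, and within-clade z-scores, with rows ordered to match
the tip order of a pruned phylogeny.

Filtering rules applied during aggregation:

* a species is retained only with at least two yawns from at least two
  different individuals;
* an explicit exclusion list (e.g. domesticated species whose brain
  measures vary strongly by breed, or species that cannot be placed in
  the tree) removes species by name;
* every drop is recorded with a reason in a :class:`DropLog`.

Endocranial volume is converted to brain mass as ``mass = 1.036 * ECV``;
a directly measured brain mass takes precedence over the conversion.
Neuronal density is ``total_neurons / brain_mass`` (neurons per gram),
computed before the log transform.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .exceptions import (
    DomainError,
    EmptyInputError,
    FormatError,
    InputError,
    InsufficientDataError,
)

__all__ = [
    "YawnEvent",
    "DropLog",
    "canonical_name",
    "read_yawn_events",
    "read_species_records",
    "write_events",
    "ecv_to_brain_mass",
    "aggregate_species",
    "match_tree",
    "Z_MEASURES",
]

ECV_TO_MASS = 1.036  # grams of brain per millilitre of endocranial volume

#: log-scale measures that receive within-clade z-score columns
Z_MEASURES = [
    "log_body",
    "log_brain",
    "log_total_neurons",
    "log_cortex_neurons",
    "log_neuron_density",
]


@dataclass(frozen=True)
class YawnEvent:
    """One observed yawn: species, individual, duration in seconds."""

    species_id: str
    individual_id: str
    duration: float
    source: str = ""

    def __post_init__(self):
        if not self.species_id or not self.individual_id:
            raise InputError("species_id and individual_id must be non-empty")
        if not (self.duration > 0):
            raise DomainError(f"yawn duration must be positive; got {self.duration}")


class DropLog:
    """Accumulates dropped/rejected items with reasons; JSON-serializable."""

    def __init__(self):
        self.entries: list[dict] = []

    def record(self, stage: str, item: str, reason: str):
        self.entries.append({"stage": stage, "item": str(item), "reason": reason})

    def items(self, stage: str | None = None) -> list[dict]:
        if stage is None:
            return list(self.entries)
        return [e for e in self.entries if e["stage"] == stage]

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(self.entries, fh, indent=2)

    def __len__(self):
        return len(self.entries)


def canonical_name(name: str) -> str:
    """Canonical species key: trimmed, internal whitespace collapsed to a
    single underscore, case-insensitive."""
    return re.sub(r"[\s_]+", "_", str(name).strip()).casefold()


def _find_column(df: pd.DataFrame, aliases: list[str], required_name: str) -> str:
    lower = {str(c).strip().casefold(): c for c in df.columns}
    for a in aliases:
        if a in lower:
            return lower[a]
    raise FormatError(f"missing required column: {required_name}")


def read_yawn_events(path, drop_log: DropLog | None = None) -> list[YawnEvent]:
    """Read per-yawn events from a CSV with species/individual/duration columns.

    Rows with a non-numeric or non-positive duration, or with an empty
    species or individual field, are rejected and recorded in ``drop_log``.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"empty events file: {path}")
    if df.empty:
        raise EmptyInputError(f"events file has no data rows: {path}")

    sp_col = _find_column(df, ["species", "species_id"], "species")
    ind_col = _find_column(df, ["individual", "individual_id"], "individual")
    dur_col = _find_column(
        df, ["duration", "duration_s", "duration_seconds"], "duration"
    )
    src_col = None
    for cand in ("source", "origin"):
        if cand in {str(c).strip().casefold() for c in df.columns}:
            src_col = _find_column(df, [cand], cand)
            break

    events: list[YawnEvent] = []
    for idx, row in df.iterrows():
        sp = str(row[sp_col]).strip()
        ind = str(row[ind_col]).strip()
        dur = pd.to_numeric(row[dur_col], errors="coerce")
        if not sp or sp.lower() == "nan" or not ind or ind.lower() == "nan":
            if drop_log is not None:
                drop_log.record("read_events", f"row {idx}", "empty species or individual")
            continue
        if pd.isna(dur) or dur <= 0:
            if drop_log is not None:
                drop_log.record(
                    "read_events", f"row {idx} ({sp})",
                    f"non-positive or non-numeric duration: {row[dur_col]!r}",
                )
            continue
        src = "" if src_col is None else str(row[src_col])
        events.append(YawnEvent(sp, ind, float(dur), src))
    return events


def write_events(events: list[YawnEvent], path) -> None:
    """Write events as CSV (species, individual, duration, source)."""
    df = pd.DataFrame(
        {
            "species": [e.species_id for e in events],
            "individual": [e.individual_id for e in events],
            "duration": [e.duration for e in events],
            "source": [e.source for e in events],
        }
    )
    # %.17g guarantees the duration round-trips bit-exactly through text
    df.to_csv(path, index=False, float_format="%.17g")


def ecv_to_brain_mass(ecv: float) -> float:
    """Brain mass (g) from endocranial volume (ml): ``1.036 * ecv``."""
    arr = np.asarray(ecv, dtype=float)
    if np.any(~(arr > 0)):
        raise DomainError(f"endocranial volume must be positive; got {ecv}")
    out = ECV_TO_MASS * arr
    return float(out) if np.isscalar(ecv) or arr.ndim == 0 else out


_OPTIONAL_NUMERIC = ["brain_mass", "ecv", "total_neurons", "cortex_pallium_neurons"]


def read_species_records(path, drop_log: DropLog | None = None) -> pd.DataFrame:
    """Read the species trait table.

    Required columns: species, clade, body_mass.  Optional: order,
    brain_mass, ecv, total_neurons, cortex_pallium_neurons.  Rows lacking
    both brain_mass and ecv, or with non-positive masses/counts, are
    dropped with a logged reason.
    """
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"empty traits file: {path}")
    if df.empty:
        raise EmptyInputError(f"traits file has no data rows: {path}")

    sp_col = _find_column(df, ["species", "species_id"], "species")
    clade_col = _find_column(df, ["clade"], "clade")
    body_col = _find_column(df, ["body_mass", "body_mass_g"], "body_mass")

    out = pd.DataFrame()
    out["species"] = df[sp_col].astype(str).str.strip()
    out["clade"] = df[clade_col].astype(str).str.strip().str.lower()
    lower = {str(c).strip().casefold(): c for c in df.columns}
    out["order"] = (
        df[lower["order"]].astype(str).str.strip() if "order" in lower else ""
    )
    out["body_mass"] = pd.to_numeric(df[body_col], errors="coerce")
    for col in _OPTIONAL_NUMERIC:
        out[col] = (
            pd.to_numeric(df[lower[col]], errors="coerce")
            if col in lower
            else np.nan
        )

    bad_clade = ~out["clade"].isin(["mammal", "bird"])
    keep = np.ones(len(out), dtype=bool)
    for i, row in out.iterrows():
        reasons = []
        if bad_clade[i]:
            reasons.append(f"unknown clade {row['clade']!r}")
        if not (row["body_mass"] > 0):
            reasons.append("missing or non-positive body mass")
        if not (row["brain_mass"] > 0) and not (row["ecv"] > 0):
            reasons.append("neither brain mass nor ECV present")
        for col in ("total_neurons", "cortex_pallium_neurons"):
            if not pd.isna(row[col]) and row[col] <= 0:
                reasons.append(f"non-positive {col}")
        if reasons:
            keep[i] = False
            if drop_log is not None:
                drop_log.record("read_records", row["species"], "; ".join(reasons))
    out = out[keep].reset_index(drop=True)
    if out.empty:
        raise EmptyInputError(f"no valid species rows in {path}")
    return out


def _zscore_within_clade(table: pd.DataFrame) -> pd.DataFrame:
    for col in Z_MEASURES:
        zcol = "z_" + col.removeprefix("log_")
        table[zcol] = np.nan
        for _, idx in table.groupby("clade").groups.items():
            vals = table.loc[idx, col]
            ok = vals.notna()
            if ok.sum() >= 2 and vals[ok].std(ddof=1) > 0:
                table.loc[idx[ok], zcol] = (
                    vals[ok] - vals[ok].mean()
                ) / vals[ok].std(ddof=1)
    return table


def aggregate_species(
    events: list[YawnEvent],
    records: pd.DataFrame,
    exclusions: list[str] | tuple = (),
    drop_log: DropLog | None = None,
    mean_over: str = "yawns",
) -> pd.DataFrame:
    """Build the per-species analysis table from events and trait records.

    Retains a species only if it has >= 2 yawns from >= 2 different
    individuals and is not on the exclusion list.  The species mean yawn
    duration averages over all yawns (``mean_over='yawns'``) or over
    per-individual means (``mean_over='individuals'``).  Event species
    absent from ``records`` are reported as unmatched in ``drop_log``.
    """
    if mean_over not in ("yawns", "individuals"):
        raise InputError(f"mean_over must be 'yawns' or 'individuals'; got {mean_over}")
    if not events:
        raise EmptyInputError("no yawn events supplied")

    excl = {canonical_name(s) for s in exclusions}
    rec = records.copy()
    if "order" not in rec.columns:
        rec["order"] = ""
    for col in _OPTIONAL_NUMERIC:
        if col not in rec.columns:
            rec[col] = np.nan
    rec["key"] = rec["species"].map(canonical_name)
    rec = rec.drop_duplicates(subset="key").set_index("key")

    ev = pd.DataFrame(
        {
            "key": [canonical_name(e.species_id) for e in events],
            "individual": [e.individual_id for e in events],
            "duration": [e.duration for e in events],
        }
    )

    rows = []
    for key, grp in ev.groupby("key", sort=True):
        if key in excl:
            if drop_log is not None:
                drop_log.record("aggregate", key, "on exclusion list")
            continue
        if key not in rec.index:
            if drop_log is not None:
                drop_log.record("aggregate", key, "unmatched: species not in trait records")
            continue
        n_yawns = len(grp)
        n_ind = grp["individual"].nunique()
        if n_yawns < 2 or n_ind < 2:
            if drop_log is not None:
                drop_log.record(
                    "aggregate", key,
                    f"fewer than 2 yawns from 2 individuals (yawns={n_yawns}, individuals={n_ind})",
                )
            continue
        if mean_over == "yawns":
            mean_dur = float(grp["duration"].mean())
        else:
            mean_dur = float(grp.groupby("individual")["duration"].mean().mean())

        r = rec.loc[key]
        brain = r["brain_mass"]
        if not (brain > 0):
            brain = ecv_to_brain_mass(float(r["ecv"]))
        row = {
            "species": key,
            "clade": r["clade"],
            "order": r["order"],
            "mean_yawn_duration": mean_dur,
            "n_yawns": n_yawns,
            "n_individuals": int(n_ind),
            "body_mass": float(r["body_mass"]),
            "brain_mass": float(brain),
            "total_neurons": float(r["total_neurons"]) if r["total_neurons"] > 0 else np.nan,
            "cortex_pallium_neurons": (
                float(r["cortex_pallium_neurons"]) if r["cortex_pallium_neurons"] > 0 else np.nan
            ),
        }
        row["neuron_density"] = (
            row["total_neurons"] / row["brain_mass"]
            if not math.isnan(row["total_neurons"])
            else np.nan
        )
        row["log_body"] = math.log(row["body_mass"])
        row["log_brain"] = math.log(row["brain_mass"])
        row["log_total_neurons"] = (
            math.log(row["total_neurons"]) if not math.isnan(row["total_neurons"]) else np.nan
        )
        row["log_cortex_neurons"] = (
            math.log(row["cortex_pallium_neurons"])
            if not math.isnan(row["cortex_pallium_neurons"])
            else np.nan
        )
        row["log_neuron_density"] = (
            math.log(row["neuron_density"]) if not math.isnan(row["neuron_density"]) else np.nan
        )
        rows.append(row)

    if not rows:
        raise EmptyInputError("no species survive the aggregation filters")
    table = pd.DataFrame(rows).reset_index(drop=True)
    return _zscore_within_clade(table)


def match_tree(
    table: pd.DataFrame, tree: dendropy.Tree, drop_log: DropLog | None = None
):
    """Prune the tree to the table's species and reorder the table to tip order.

    Matching is by canonical species name.  Species absent from the tree
    are dropped with a logged reason; fewer than 4 matches is an error
    (the phylogenetic model is unidentifiable below that).
    Returns ``(pruned_tree, reordered_table)``.
    """
    tip_by_key = {}
    for leaf in tree.leaf_node_iter():
        tip_by_key[canonical_name(leaf.taxon.label)] = leaf.taxon.label

    keys = table["species"].map(canonical_name)
    in_tree = keys.isin(tip_by_key)
    for sp in table.loc[~in_tree, "species"]:
        if drop_log is not None:
            drop_log.record("match_tree", sp, "species not found in tree")
    matched = table[in_tree].copy()
    matched["species"] = keys[in_tree].values
    if len(matched) < 4:
        raise InsufficientDataError(
            f"only {len(matched)} species matched to the tree; >= 4 required"
        )

    labels = [tip_by_key[k] for k in matched["species"]]
    pruned = tree.extract_tree_with_taxa_labels(labels=labels)
    # canonicalize tip labels on the pruned copy
    for leaf in pruned.leaf_node_iter():
        leaf.taxon.label = canonical_name(leaf.taxon.label)
    tip_order = [leaf.taxon.label for leaf in pruned.leaf_node_iter()]
    matched = matched.set_index("species").loc[tip_order].reset_index()
    return pruned, matched
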