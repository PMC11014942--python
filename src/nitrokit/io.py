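"""Table readers/writers, config loading, and run reports.

One CSV dialect throughout: comma-delimited, UTF-8, header row required,
"." decimal, missing values as empty strings. Malformed values raise with
file and row context instead of being coerced.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, ParseError, SchemaError
from .inventory import AnnotationTable, GeneProcessMap
from .isotopes import Endmember, IsotopeMeasurement, SampleType
from .sip import SIPProfile

ISOTOPE_COLUMNS = [
    "sample_id",
    "sample_type",
    "d18O",
    "d17O",
    "D17O",
    "d15N",
    "sigma_d18O",
    "sigma_D17O",
    "sigma_d15N",
]

SIP_COLUMNS = [
    "treatment",
    "temperature_C",
    "target_gene",
    "replicate",
    "density_g_per_mL",
    "abundance",
]


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pandas raises several parser classes
        raise ParseError(f"{path}: {exc}") from exc
    if df.columns.size == 0 or all(c.startswith("Unnamed") for c in df.columns):
        raise SchemaError(f"{path}: no header row found")
    return df


def _float_or_none(
    raw: str, path: Path, row: int, col: str
) -> float | None:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError as exc:
        raise ParseError(
            f"{path}, row {row}, column {col!r}: not a number: {raw!r}"
        ) from exc


def read_isotope_table(path: str | Path) -> list[IsotopeMeasurement]:
    """Parse an isotope measurement CSV into domain records."""
    path = Path(path)
    df = _read_csv(path)
    missing = {"sample_id", "sample_type", "d18O"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    out: list[IsotopeMeasurement] = []
    for i, rec in enumerate(df.to_dict("records")):
        row = i + 2  # header is row 1
        kwargs: dict = {
            "sample_id": str(rec["sample_id"]),
        }
        stype = str(rec["sample_type"]).strip()
        try:
            kwargs["sample_type"] = SampleType(stype)
        except ValueError as exc:
            raise ParseError(
                f"{path}, row {row}: unknown sample_type {stype!r}"
            ) from exc
        d18O = _float_or_none(str(rec["d18O"]), path, row, "d18O")
        if d18O is None:
            raise ParseError(f"{path}, row {row}: d18O is required")
        kwargs["d18O"] = d18O
        for col in ("d17O", "D17O", "d15N"):
            if col in df.columns:
                kwargs[col] = _float_or_none(str(rec[col]), path, row, col)
        for col in ("sigma_d18O", "sigma_D17O", "sigma_d15N"):
            if col in df.columns:
                v = _float_or_none(str(rec[col]), path, row, col)
                if v is not None:
                    kwargs[col] = v
        out.append(IsotopeMeasurement(**kwargs))
    return out


def write_isotope_table(measurements, path: str | Path) -> None:
    rows = []
    for m in measurements:
        rows.append(
            {
                "sample_id": m.sample_id,
                "sample_type": m.sample_type.value,
                "d18O": m.d18O,
                "d17O": "" if m.d17O is None else m.d17O,
                "D17O": "" if m.D17O is None else m.D17O,
                "d15N": "" if m.d15N is None else m.d15N,
                "sigma_d18O": m.sigma_d18O,
                "sigma_D17O": m.sigma_D17O,
                "sigma_d15N": m.sigma_d15N,
            }
        )
    pd.DataFrame(rows, columns=ISOTOPE_COLUMNS).to_csv(path, index=False)


def read_endmembers(path: str | Path) -> tuple[Endmember, Endmember]:
    """Load the (biological, atmospheric) endmember pair from YAML."""
    path = Path(path)
    try:
        cfg = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: endmember file must be a mapping")
    ems = {}
    for name in ("biological", "atmospheric"):
        if name not in cfg:
            raise SchemaError(f"{path}: missing endmember {name!r}")
        block = cfg[name]
        try:
            ems[name] = Endmember(
                name=name,
                d18O=float(block["d18O"]),
                sigma_d18O=float(block.get("sigma_d18O", 0.0)),
                D17O=float(block.get("D17O", 0.0)),
                sigma_D17O=float(block.get("sigma_D17O", 0.0)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: bad endmember block {name!r}: {exc}") from exc
    return ems["biological"], ems["atmospheric"]


def read_panel(path: str | Path) -> GeneProcessMap:
    """Load a process -> marker-genes panel from YAML."""
    path = Path(path)
    try:
        cfg = yaml.safe_load(path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not isinstance(cfg, dict) or "processes" not in cfg:
        raise SchemaError(f"{path}: panel file needs a 'processes' mapping")
    processes: dict[str, frozenset[str]] = {}
    rules: dict[str, str] = {}
    for proc, block in cfg["processes"].items():
        if isinstance(block, dict):
            genes = block.get("genes", [])
            if "rule" in block:
                rules[proc] = str(block["rule"])
        else:
            genes = block
        if not isinstance(genes, (list, tuple)):
            raise SchemaError(f"{path}: genes for {proc!r} must be a list")
        processes[proc] = frozenset(str(g) for g in genes)
    return GeneProcessMap(processes, rules)


def packaged_panel(name: str) -> GeneProcessMap:
    """Load one of the shipped panels ('ncycle' or 'energy')."""
    ref = resources.files("nitrokit.data") / f"{name}.yaml"
    with resources.as_file(ref) as p:
        return read_panel(p)


def packaged_endmembers() -> tuple[Endmember, Endmember]:
    """The shipped Antarctic endmember constants (92/0.6/32/0 permil)."""
    ref = resources.files("nitrokit.data") / "endmembers.yaml"
    with resources.as_file(ref) as p:
        return read_endmembers(p)


def read_annotation_table(
    path: str | Path, value_kind: str = "copies_per_ng"
) -> AnnotationTable:
    """Rows = samples/genomes, columns = gene symbols, numeric values."""
    path = Path(path)
    df = _read_csv(path)
    first = df.columns[0]
    df = df.set_index(first)
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        for i, raw in enumerate(df[col]):
            v = _float_or_none(str(raw), path, i + 2, col)
            if v is None:
                raise ParseError(f"{path}, row {i + 2}, column {col!r}: empty value")
        numeric[col] = df[col].astype(float)
    try:
        return AnnotationTable(numeric, value_kind=value_kind)
    except SchemaError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def read_sip_table(path: str | Path) -> list[SIPProfile]:
    """Parse a long-format SIP CSV into per-replicate profiles."""
    path = Path(path)
    df = _read_csv(path)
    missing = set(SIP_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    for col in ("temperature_C", "density_g_per_mL", "abundance"):
        for i, raw in enumerate(df[col]):
            if _float_or_none(str(raw), path, i + 2, col) is None:
                raise ParseError(f"{path}, row {i + 2}, column {col!r}: empty value")
        df[col] = df[col].astype(float)
    profiles: list[SIPProfile] = []
    keys = ["treatment", "temperature_C", "target_gene", "replicate"]
    for (treat, temp, gene, rep), sub in df.groupby(keys, sort=True):
        sub = sub.sort_values("density_g_per_mL")
        profiles.append(
            SIPProfile(
                treatment=str(treat),
                temperature_C=float(temp),
                densities=tuple(sub["density_g_per_mL"]),
                abundances=tuple(sub["abundance"]),
                target_gene=str(gene),
                replicate=int(rep),
            )
        )
    return profiles


def write_sip_table(profiles, path: str | Path) -> None:
    rows = []
    for p in profiles:
        for d, a in zip(p.densities, p.abundances):
            rows.append(
                {
                    "treatment": p.treatment,
                    "temperature_C": p.temperature_C,
                    "target_gene": p.target_gene,
                    "replicate": p.replicate if p.replicate is not None else 1,
                    "density_g_per_mL": d,
                    "abundance": a,
                }
            )
    pd.DataFrame(rows, columns=SIP_COLUMNS).to_csv(path, index=False)


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_run_report(
    path: str | Path,
    subcommand: str,
    inputs: dict[str, str],
    config: dict,
    seed: int | None = None,
) -> None:
    """JSON provenance record: version, config echo, input digests, seed.

    Config + inputs + seed fully determine the run's outputs; the
    timestamp is informational only.
    """
    report = {
        "tool": "nitrokit",
        "version": __version__,
        "subcommand": subcommand,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "config": config,
        "input_digests": {k: file_digest(v) for k, v in inputs.items()},
    }
    Path(path).write_text(json.dumps(report, indent=2) + "\n", encoding="utf-8")
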