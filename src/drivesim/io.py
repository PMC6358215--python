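"""Reading and writing phenotype count tables, and run configuration.

Count tables are UTF-8 TSV with the header ``sex dsred egfp body count`` and
lower-case categorical values (``female/male``, ``true/false``,
``full/mosaic/none/na``, ``wild/yellow/mosaic_yellow``) — one row per
phenotype class, mirroring how flies are tallied at the microscope.
Metadata (design name, number of crosses pooled) rides in ``#``-prefixed
header comments so that a written table reads back identically.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

from .simulate import CountTable

__all__ = [
    "CountTableFormatError",
    "read_count_table",
    "write_count_table",
    "count_table_from_frame",
    "count_table_to_frame",
    "RunConfig",
]

_COLUMNS = ("sex", "dsred", "egfp", "body", "count")
_VALID = {
    "sex": {"female", "male"},
    "dsred": {"true", "false"},
    "egfp": {"full", "mosaic", "none", "na"},
    "body": {"wild", "yellow", "mosaic_yellow"},
}


class CountTableFormatError(ValueError):
    """Malformed count-table file (bad header, labels, counts or keys)."""


def _parse_row(fields: list[str], lineno: int) -> tuple[tuple[str, bool, str, str], int]:
    if len(fields) != 5:
        raise CountTableFormatError(
            f"line {lineno}: expected 5 tab-separated fields, got {len(fields)}"
        )
    sex, dsred, egfp, body, count_s = (f.strip() for f in fields)
    for col, value in zip(_COLUMNS[:4], (sex, dsred, egfp, body)):
        if value not in _VALID[col]:
            raise CountTableFormatError(
                f"line {lineno}: unknown {col} label {value!r}"
            )
    try:
        count = int(count_s)
    except ValueError:
        raise CountTableFormatError(
            f"line {lineno}: count {count_s!r} is not an integer"
        ) from None
    if count < 0:
        raise CountTableFormatError(f"line {lineno}: negative count {count}")
    return (sex, dsred == "true", egfp, body), count


def read_count_table(path: str | Path) -> CountTable:
    """Parse a count-table TSV; rejects malformed rows with their line number."""
    path = Path(path)
    table = CountTable()
    seen: set[tuple] = set()
    with path.open("r", encoding="utf-8") as fh:
        header_done = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                meta = line[1:].strip()
                if meta.startswith("design:"):
                    table.name = meta.split(":", 1)[1].strip()
                elif meta.startswith("n_crosses:"):
                    try:
                        table.n_crosses = int(meta.split(":", 1)[1])
                    except ValueError:
                        raise CountTableFormatError(
                            f"line {lineno}: bad n_crosses metadata"
                        ) from None
                continue
            fields = line.split("\t")
            if not header_done:
                if tuple(f.strip() for f in fields) != _COLUMNS:
                    raise CountTableFormatError(
                        f"line {lineno}: header must be {' '.join(_COLUMNS)!r}"
                    )
                header_done = True
                continue
            key, count = _parse_row(fields, lineno)
            if key in seen:
                raise CountTableFormatError(
                    f"line {lineno}: duplicate phenotype class {key}"
                )
            seen.add(key)
            table.add_key(key, count)
    if not header_done:
        raise CountTableFormatError(f"{path}: missing header line")
    return table


def _format_table(t: CountTable) -> str:
    buf = _io.StringIO()
    if t.name:
        buf.write(f"# design: {t.name}\n")
    buf.write(f"# n_crosses: {t.n_crosses}\n")
    buf.write("\t".join(_COLUMNS) + "\n")
    for (sex, dsred, egfp, body), count in sorted(
        t.counts.items(), key=lambda kv: kv[0]
    ):
        if count == 0:
            continue
        buf.write(
            f"{sex}\t{'true' if dsred else 'false'}\t{egfp}\t{body}\t{count}\n"
        )
    return buf.getvalue()


def write_count_table(t: CountTable, path: str | Path) -> None:
    """Write a count table; round-trips exactly through :func:`read_count_table`."""
    Path(path).write_text(_format_table(t), encoding="utf-8")


def count_table_from_frame(df, name: str = "") -> CountTable:
    """Build a CountTable from a DataFrame with the TSV columns."""
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise CountTableFormatError(f"missing columns: {missing}")
    table = CountTable(name=name)
    seen: set[tuple] = set()
    for _, row in df.iterrows():
        dsred = row["dsred"]
        if isinstance(dsred, str):
            dsred = dsred.strip() == "true"
        key = (str(row["sex"]), bool(dsred), str(row["egfp"]), str(row["body"]))
        count = int(row["count"])
        if count < 0:
            raise CountTableFormatError(f"negative count {count}")
        if key in seen:
            raise CountTableFormatError(f"duplicate phenotype class {key}")
        seen.add(key)
        table.add_key(key, count)
    return table


def count_table_to_frame(t: CountTable):
    import pandas as pd

    rows = [
        {"sex": sex, "dsred": "true" if dsred else "false",
         "egfp": egfp, "body": body, "count": count}
        for (sex, dsred, egfp, body), count in sorted(t.counts.items())
        if count
    ]
    return pd.DataFrame(rows, columns=list(_COLUMNS))


@dataclass
class RunConfig:
    """Validated run configuration for simulation commands.

    A flat key-value YAML document mirrors these fields; command-line flags
    override file values.  Probability fields are validated (by constructing
    the DriveParams) before any simulation starts.
    """

    seed: int = 1
    design: str = "D2"
    n_crosses: int = 40
    n_per_cross: int = 100
    replicates: int = 50
    params: dict = field(default_factory=dict)
    output: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a flat mapping")
        known = {f for f in cls.__dataclass_fields__}
        cfg: dict = {"params": {}}
        from .simulate import DriveParams

        param_fields = set(DriveParams.__dataclass_fields__)
        for key, value in raw.items():
            if key in param_fields:
                cfg["params"][key] = float(value)
            elif key in known:
                cfg[key] = value
            else:
                raise ValueError(f"{path}: unknown config key {key!r}")
        for key, value in overrides.items():
            if value is None:
                continue
            if key in param_fields:
                cfg["params"][key] = float(value)
            else:
                cfg[key] = value
        return cls(**cfg)

    def drive_params(self):
        from .simulate import DriveParams

        return DriveParams(**self.params)
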