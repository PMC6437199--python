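"""Event-level cytometry I/O: a minimal FCS dialect, a CSV fallback and the
sample manifest.

The pipeline consumes five canonical channels per event:

========  =====================================================
channel   meaning
========  =====================================================
FSC       forward scatter (cell size proxy)
SSC       side scatter (granularity proxy)
GFP       transfection reporter fluorescence
PE        phycoerythrin — anti-human-IgG secondary antibody
AAD       7-aminoactinomycin D viability dye
========  =====================================================

Instrument channel names vary (``FL1-A``, ``FITC`` ...), so both readers map
names through a built-in alias table that the caller can extend.

The FCS support is deliberately a small dialect: FCS 3.0/3.1 on read,
FCS 3.1 on write — single dataset, list mode, linear float32 data,
little-endian by default.  Spillover compensation, log amplifiers and
multi-dataset files are out of scope.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .errors import (
    CalibrationPrerequisiteError,
    ChannelMappingError,
    FormatError,
    PairingError,
    ValidationError,
)

#: Canonical channel order; every EventTable stores exactly these columns.
CHANNELS: tuple[str, ...] = ("FSC", "SSC", "GFP", "PE", "AAD")

CELL_LINES = ("parental", "transfected")
ANTIGENS = ("titin", "ryr", "kv14", "none")
ROLES = ("test", "no_serum_no_secondary", "no_serum_with_secondary")

#: Built-in instrument-name aliases, keyed by canonical channel.  Matching is
#: case-insensitive and ignores ``-A``/``-H``/``-W`` pulse suffixes.
DEFAULT_ALIASES: dict[str, tuple[str, ...]] = {
    "FSC": ("FSC", "FS", "FS LIN", "FORWARD SCATTER"),
    "SSC": ("SSC", "SS", "SS LIN", "SIDE SCATTER"),
    "GFP": ("GFP", "FL1", "FITC", "EGFP"),
    "PE": ("PE", "FL2"),
    "AAD": ("AAD", "7AAD", "7-AAD", "7_AAD", "FL3", "PERCP"),
}


def _normalise_channel_name(name: str) -> str:
    name = name.strip().upper()
    for suffix in ("-A", "-H", "-W"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
    return name


def map_channel_name(name: str, aliases: dict[str, tuple[str, ...]] | None = None) -> str:
    """Map an instrument channel name to one of :data:`CHANNELS`.

    Raises :class:`ChannelMappingError` listing the aliases tried if the name
    is not recognised.
    """
    table = dict(DEFAULT_ALIASES)
    if aliases:
        for canon, extra in aliases.items():
            table[canon] = tuple(table.get(canon, ())) + tuple(extra)
    norm = _normalise_channel_name(name)
    for canon, names in table.items():
        if norm == canon or norm in {_normalise_channel_name(a) for a in names}:
            return canon
    tried = {c: sorted({c, *(_normalise_channel_name(a) for a in a_list)})
             for c, a_list in table.items()}
    raise ChannelMappingError(
        f"channel name {name!r} not recognised; aliases tried: {tried}"
    )


@dataclass
class EventTable:
    """Per-event channel intensities plus sample metadata.

    ``intensities`` is an ``(n_events, 5)`` float array in the canonical
    channel order of :data:`CHANNELS`; all values are finite and >= 0.
    """

    sample_id: str
    cell_line: str
    antigen: str
    intensities: np.ndarray
    serum_id: str | None = None
    dilution: int | None = None
    cell_count_nominal: int = 5_000_000

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2 or self.intensities.shape[1] != len(CHANNELS):
            raise ValidationError(
                f"intensities must be (n_events, {len(CHANNELS)}); "
                f"got shape {self.intensities.shape}"
            )
        if self.cell_line not in CELL_LINES:
            raise ValidationError(f"unknown cell_line {self.cell_line!r}")
        if self.antigen not in ANTIGENS:
            raise ValidationError(f"unknown antigen {self.antigen!r}")
        if self.dilution is not None and self.dilution <= 0:
            raise ValidationError("dilution must be a positive reciprocal")
        if self.cell_count_nominal <= 0:
            raise ValidationError("cell_count_nominal must be positive")
        if self.intensities.size and not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensities must be finite")
        if self.intensities.size and self.intensities.min() < 0:
            raise ValidationError("intensities must be non-negative")

    @property
    def n_events(self) -> int:
        return self.intensities.shape[0]

    def channel(self, name: str) -> np.ndarray:
        """Return the intensity column for a canonical channel name."""
        return self.intensities[:, CHANNELS.index(name)]

    def with_intensities(self, intensities: np.ndarray) -> "EventTable":
        return replace(self, intensities=intensities)

    def _metadata(self) -> dict[str, str]:
        meta = {
            "sample_id": self.sample_id,
            "cell_line": self.cell_line,
            "antigen": self.antigen,
            "cell_count_nominal": str(self.cell_count_nominal),
        }
        if self.serum_id is not None:
            meta["serum_id"] = self.serum_id
        if self.dilution is not None:
            meta["dilution"] = str(self.dilution)
        return meta


# ---------------------------------------------------------------------------
# FCS dialect
# ---------------------------------------------------------------------------

_FCS_DELIM = "/"
_META_KEYWORDS = {
    "sample_id": "CBA_SAMPLE_ID",
    "cell_line": "CBA_CELL_LINE",
    "antigen": "CBA_ANTIGEN",
    "serum_id": "CBA_SERUM_ID",
    "dilution": "CBA_DILUTION",
    "cell_count_nominal": "CBA_CELL_COUNT",
}


def write_fcs(table: EventTable, path: str | Path) -> None:
    """Write an FCS 3.1 file: one dataset, list mode, little-endian float32.

    Sample metadata is stored under ``CBA_*`` custom TEXT keywords and
    round-trips through :func:`read_fcs`.
    """
    data = np.ascontiguousarray(table.intensities, dtype="<f4")
    n_events, n_par = data.shape
    ranges = [int(np.ceil(data[:, i].max())) + 1 if n_events else 1024
              for i in range(n_par)]

    keywords: list[tuple[str, str]] = [
        ("$BEGINANALYSIS", "0"), ("$ENDANALYSIS", "0"),
        ("$BEGINSTEXT", "0"), ("$ENDSTEXT", "0"),
        # fixed-width so TEXT length is independent of the actual offsets
        ("$BEGINDATA", "%012d"), ("$ENDDATA", "%012d"),
        ("$BYTEORD", "1,2,3,4"), ("$DATATYPE", "F"), ("$MODE", "L"),
        ("$NEXTDATA", "0"),
        ("$TOT", str(n_events)), ("$PAR", str(n_par)),
    ]
    for i, name in enumerate(CHANNELS, start=1):
        keywords += [(f"$P{i}N", name), (f"$P{i}B", "32"),
                     (f"$P{i}E", "0,0"), (f"$P{i}R", str(ranges[i - 1]))]
    for meta_key, fcs_key in _META_KEYWORDS.items():
        value = table._metadata().get(meta_key)
        if value is not None:
            keywords.append((fcs_key, value))

    for key, value in keywords:
        if _FCS_DELIM in value:
            raise FormatError(f"keyword value {value!r} contains the TEXT delimiter")

    def render(begin_data: int, end_data: int) -> bytes:
        parts = [_FCS_DELIM]
        for key, value in keywords:
            if key == "$BEGINDATA":
                value = "%012d" % begin_data
            elif key == "$ENDDATA":
                value = "%012d" % end_data
            parts.append(f"{key}{_FCS_DELIM}{value}{_FCS_DELIM}")
        return "".join(parts).encode("ascii")

    header_len = 58
    text = render(0, 0)
    text_start = header_len
    text_end = text_start + len(text) - 1
    data_start = text_end + 1
    data_end = data_start + data.nbytes - 1 if data.nbytes else 0
    text = render(data_start, data_end)

    header = b"FCS3.1    " + b"".join(
        b"%8d" % v for v in (text_start, text_end,
                             data_start if data.nbytes else 0,
                             data_end, 0, 0)
    )
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())


def _parse_fcs_text(raw: bytes) -> dict[str, str]:
    delim = chr(raw[0])
    # the final delimiter terminates the segment; split on the rest
    body = raw.decode("ascii", errors="replace").strip(delim)
    tokens = body.split(delim)
    if len(tokens) % 2:
        tokens = tokens[:-1]
    return {tokens[i].strip(): tokens[i + 1] for i in range(0, len(tokens), 2)}


def read_fcs(path: str | Path,
             aliases: dict[str, tuple[str, ...]] | None = None) -> EventTable:
    """Read a single-dataset FCS 3.0/3.1 file into an :class:`EventTable`.

    Channel names are mapped through the alias table; intensities are clipped
    at zero (negative compensated values are out of scope).
    """
    raw = Path(path).read_bytes()
    if len(raw) < 58:
        raise FormatError(f"{path}: file too short for an FCS header")
    version = raw[:6].decode("ascii", errors="replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FormatError(f"{path}: unsupported FCS version {version!r}")
    try:
        text_start = int(raw[10:18])
        text_end = int(raw[18:26])
        data_start = int(raw[26:34])
        data_end = int(raw[34:42])
    except ValueError as exc:
        raise FormatError(f"{path}: malformed HEADER offsets") from exc

    keywords = _parse_fcs_text(raw[text_start:text_end + 1])
    for required in ("$TOT", "$PAR", "$DATATYPE", "$BYTEORD"):
        if required not in keywords:
            raise FormatError(f"{path}: missing required keyword {required}")

    n_events = int(keywords["$TOT"])
    n_par = int(keywords["$PAR"])
    datatype = keywords["$DATATYPE"].strip().upper()
    byteord = keywords["$BYTEORD"].strip()
    if byteord in ("1,2,3,4", "1,2"):
        endian = "<"
    elif byteord in ("4,3,2,1", "2,1"):
        endian = ">"
    else:
        raise FormatError(f"{path}: unsupported $BYTEORD {byteord!r}")

    names = []
    for i in range(1, n_par + 1):
        key = f"$P{i}N"
        if key not in keywords:
            raise FormatError(f"{path}: missing required keyword {key}")
        names.append(keywords[key])

    if not data_start and "$BEGINDATA" in keywords:
        data_start = int(keywords["$BEGINDATA"])
        data_end = int(keywords["$ENDDATA"])

    if datatype == "F":
        dtype = np.dtype(endian + "f4")
    elif datatype == "D":
        dtype = np.dtype(endian + "f8")
    elif datatype == "I":
        bits = {keywords.get(f"$P{i}B", "32") for i in range(1, n_par + 1)}
        if len(bits) != 1 or bits.pop() not in ("16", "32"):
            raise FormatError(f"{path}: only uniform 16/32-bit integer data supported")
        width = int(keywords["$P1B"])
        dtype = np.dtype(endian + ("u2" if width == 16 else "u4"))
    else:
        raise FormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    expected = n_events * n_par * dtype.itemsize
    blob = raw[data_start:data_start + expected] if expected else b""
    if len(blob) != expected:
        raise FormatError(f"{path}: DATA segment truncated "
                          f"({len(blob)} of {expected} bytes)")
    data = np.frombuffer(blob, dtype=dtype).astype(float).reshape(n_events, n_par)

    canonical = [map_channel_name(name, aliases) for name in names]
    if sorted(canonical) != sorted(CHANNELS):
        raise ChannelMappingError(
            f"{path}: channels {canonical} do not cover {CHANNELS}")
    order = [canonical.index(ch) for ch in CHANNELS]
    data = np.clip(data[:, order], 0.0, None)

    def kw(meta_key: str) -> str | None:
        return keywords.get(_META_KEYWORDS[meta_key])

    return EventTable(
        sample_id=kw("sample_id") or Path(path).stem,
        cell_line=kw("cell_line") or "parental",
        antigen=kw("antigen") or "none",
        intensities=data,
        serum_id=kw("serum_id"),
        dilution=int(kw("dilution")) if kw("dilution") else None,
        cell_count_nominal=int(kw("cell_count_nominal") or 5_000_000),
    )


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def write_events_csv(table: EventTable, path: str | Path) -> None:
    """Write the CSV event dialect: ``#key=value`` metadata comment lines,
    then a ``FSC,SSC,GFP,PE,AAD`` header and one row per event at full
    float precision."""
    with open(path, "w") as fh:
        for key, value in table._metadata().items():
            fh.write(f"#{key}={value}\n")
        fh.write(",".join(CHANNELS) + "\n")
        for row in table.intensities:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


def read_events_csv(path: str | Path,
                    aliases: dict[str, tuple[str, ...]] | None = None) -> EventTable:
    """Read the CSV event dialect (see :func:`write_events_csv`).

    Metadata may come from leading ``#key=value`` lines or a ``<path>.json``
    sidecar; column names are mapped through the channel alias table.
    """
    meta: dict[str, str] = {}
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta.update({k: str(v) for k, v in json.loads(sidecar.read_text()).items()})

    header: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, value = line[1:].partition("=")
                    meta[key.strip()] = value.strip()
                continue
            if header is None:
                header = [cell.strip() for cell in line.split(",")]
                continue
            values = line.split(",")
            if len(values) != len(header):
                raise FormatError(f"{path}:{lineno}: expected {len(header)} columns")
            rows.append([float(v) for v in values])

    if header is None:
        raise FormatError(f"{path}: no header row found")
    canonical = [map_channel_name(name, aliases) for name in header]
    missing = [ch for ch in CHANNELS if ch not in canonical]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")

    data = np.array(rows, dtype=float).reshape(len(rows), len(header))
    order = [canonical.index(ch) for ch in CHANNELS]
    data = data[:, order]
    if data.size and data.min() < 0:
        raise ValidationError(f"{path}: negative intensity values")

    return EventTable(
        sample_id=meta.get("sample_id", Path(path).stem),
        cell_line=meta.get("cell_line", "parental"),
        antigen=meta.get("antigen", "none"),
        intensities=data,
        serum_id=meta.get("serum_id") or None,
        dilution=int(meta["dilution"]) if meta.get("dilution") else None,
        cell_count_nominal=int(meta.get("cell_count_nominal", 5_000_000)),
    )


def read_events(path: str | Path,
                aliases: dict[str, tuple[str, ...]] | None = None) -> EventTable:
    """Dispatch on extension: ``.fcs`` files go through :func:`read_fcs`,
    anything else through :func:`read_events_csv`."""
    if str(path).lower().endswith(".fcs"):
        return read_fcs(path, aliases)
    return read_events_csv(path, aliases)


# ---------------------------------------------------------------------------
# Sample manifest
# ---------------------------------------------------------------------------

@dataclass
class ManifestEntry:
    path: str
    sample_id: str
    role: str
    cell_line: str
    antigen: str
    serum_id: str | None = None
    dilution: int | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}")
        if self.cell_line not in CELL_LINES:
            raise ValidationError(f"unknown cell_line {self.cell_line!r}")
        if self.antigen not in ANTIGENS:
            raise ValidationError(f"unknown antigen {self.antigen!r}")


@dataclass
class SampleManifest:
    """Binding of event files to assay roles.

    Invariants enforced on construction: every test (antigen, serum, dilution)
    triple has both cell lines, and every cell line x antigen combination that
    appears in a test entry has a secondary-only background control.
    """

    entries: list[ManifestEntry]

    def __post_init__(self) -> None:
        tests: dict[tuple, set[str]] = {}
        controls: set[tuple[str, str]] = set()
        for e in self.entries:
            if e.role == "test":
                tests.setdefault((e.antigen, e.serum_id, e.dilution), set()).add(e.cell_line)
            elif e.role == "no_serum_with_secondary":
                controls.add((e.cell_line, e.antigen))
        for (antigen, serum_id, dilution), lines in tests.items():
            missing = set(CELL_LINES) - lines
            if missing:
                raise PairingError(
                    f"serum {serum_id!r} (antigen {antigen}, dilution {dilution}) "
                    f"is missing its {missing.pop()} sample")
            for line in CELL_LINES:
                if (line, antigen) not in controls:
                    raise CalibrationPrerequisiteError(
                        f"no secondary-only background control for "
                        f"cell line {line!r} x antigen {antigen!r}")

    def test_groups(self) -> dict[tuple, dict[str, ManifestEntry]]:
        """Group test entries by (antigen, serum_id, dilution) -> cell_line."""
        groups: dict[tuple, dict[str, ManifestEntry]] = {}
        for e in self.entries:
            if e.role == "test":
                groups.setdefault((e.antigen, e.serum_id, e.dilution), {})[e.cell_line] = e
        return groups

    def control(self, cell_line: str, antigen: str) -> ManifestEntry:
        for e in self.entries:
            if (e.role == "no_serum_with_secondary"
                    and e.cell_line == cell_line and e.antigen == antigen):
                return e
        raise CalibrationPrerequisiteError(
            f"no secondary-only control for {cell_line} x {antigen}")


def load_manifest(path: str | Path) -> SampleManifest:
    """Load and validate a YAML or JSON sample manifest.

    The file is a list of entries with keys matching
    :class:`ManifestEntry` fields (``path, sample_id, role, cell_line,
    antigen, serum_id, dilution``).
    """
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if isinstance(raw, dict) and "entries" in raw:
        raw = raw["entries"]
    if not isinstance(raw, list):
        raise FormatError(f"{path}: manifest must be a list of entries")
    entries = []
    for item in raw:
        entries.append(ManifestEntry(
            path=item["path"],
            sample_id=item.get("sample_id", Path(item["path"]).stem),
            role=item["role"],
            cell_line=item["cell_line"],
            antigen=item["antigen"],
            serum_id=item.get("serum_id"),
            dilution=item.get("dilution"),
        ))
    return SampleManifest(entries)


def save_manifest(manifest: SampleManifest, path: str | Path) -> None:
    items = [{k: v for k, v in vars(e).items() if v is not None}
             for e in manifest.entries]
    Path(path).write_text(yaml.safe_dump(items, sort_keys=False))


# ---------------------------------------------------------------------------
# AssayRun — the paired-sample unit
# ---------------------------------------------------------------------------

@dataclass
class AssayRun:
    """One complete assay: paired test samples on both cell lines plus the
    two secondary-only background controls, with optional simulator truth."""

    serum_id: str
    antigen: str
    dilution: int
    test_parental: EventTable
    test_transfected: EventTable
    control_parental: EventTable
    control_transfected: EventTable
    replicate: int = 0
    ground_truth: dict | None = field(default=None, repr=False)

    @property
    def samples(self) -> dict[str, EventTable]:
        return {
            "test_parental": self.test_parental,
            "test_transfected": self.test_transfected,
            "control_parental": self.control_parental,
            "control_transfected": self.control_transfected,
        }


def assay_runs_from_manifest(manifest: SampleManifest,
                             base_dir: str | Path = ".",
                             aliases: dict[str, tuple[str, ...]] | None = None
                             ) -> list[AssayRun]:
    """Materialise one :class:`AssayRun` per test pair in the manifest,
    reading event files relative to ``base_dir``."""
    base = Path(base_dir)

    def load(entry: ManifestEntry) -> EventTable:
        p = Path(entry.path)
        return read_events(p if p.is_absolute() else base / p, aliases)

    runs = []
    for (antigen, serum_id, dilution), pair in sorted(
            manifest.test_groups().items(), key=lambda kv: str(kv[0])):
        runs.append(AssayRun(
            serum_id=serum_id or "",
            antigen=antigen,
            dilution=dilution or 0,
            test_parental=load(pair["parental"]),
            test_transfected=load(pair["transfected"]),
            control_parental=load(manifest.control("parental", antigen)),
            control_transfected=load(manifest.control("transfected", antigen)),
        ))
    return runs
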