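"""On-disk formats: internal FID bundles, JCAMP-DX ingest, amplitude CSVs.

Internal FID format: little-endian interleaved real/imag float64 samples in
a ``.fid`` file plus a JSON sidecar carrying the acquisition parameters,
sample id, provenance and t_start — lossless and trivially readable from
any language. JCAMP-DX support targets time-domain NTUPLES files (two AFFN
pages, real and imaginary) as produced by common spectrometer exporters;
frequency-domain JCAMP files are rejected. Amplitude tables are written as
a wide CSV (samples x targets) for statistics software plus a long-format
companion with full per-target component detail; both carry a versioned
schema header line.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .craft_workflow import TABLE_COLUMNS, AmplitudeTable
from .nmr_domain import AcquisitionParams, FIDRecord, Provenance

__all__ = [
    "FidFileBundle",
    "FORMAT_VERSION",
    "write_internal",
    "read_internal",
    "write_jcamp",
    "read_jcamp",
    "write_amplitude_csv",
    "read_amplitude_csv",
]

log = logging.getLogger(__name__)

FORMAT_VERSION = 1
_CSV_HEADER = "# fidcraft amplitude table v1"


@dataclass(frozen=True)
class FidFileBundle:
    """Paths of one stored FID: binary samples + JSON metadata sidecar."""

    data: Path
    sidecar: Path

    @classmethod
    def for_sample(cls, directory: Path | str, sample_id: str) -> "FidFileBundle":
        d = Path(directory)
        return cls(d / f"{sample_id}.fid", d / f"{sample_id}.json")


def write_internal(
    fid: FIDRecord, directory: Path | str, force: bool = False
) -> FidFileBundle:
    """Write a FID as an internal bundle; refuses to overwrite without force."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    bundle = FidFileBundle.for_sample(directory, fid.sample_id or "sample")
    for path in (bundle.data, bundle.sidecar):
        if path.exists() and not force:
            raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    interleaved = np.empty(2 * len(fid.samples), dtype="<f8")
    interleaved[0::2] = fid.samples.real
    interleaved[1::2] = fid.samples.imag
    interleaved.tofile(bundle.data)
    sidecar = {
        "version": FORMAT_VERSION,
        "sample_id": fid.sample_id,
        "provenance": fid.provenance.value,
        "t_start": fid.t_start,
        "params": {
            "spectrometer_freq": fid.params.spectrometer_freq,
            "sweep_width": fid.params.sweep_width,
            "n_points": fid.params.n_points,
            "carrier_ppm": fid.params.carrier_ppm,
            "temperature_K": fid.params.temperature_K,
        },
        "metadata": {k: v for k, v in fid.metadata.items()
                     if isinstance(v, (int, float, str, bool, list, tuple))},
    }
    bundle.sidecar.write_text(json.dumps(sidecar, indent=1))
    return bundle


def read_internal(bundle: FidFileBundle | Path | str) -> FIDRecord:
    """Read an internal FID bundle (lossless round trip)."""
    if not isinstance(bundle, FidFileBundle):
        sidecar = Path(bundle)
        if sidecar.suffix == ".fid":
            sidecar = sidecar.with_suffix(".json")
        bundle = FidFileBundle(sidecar.with_suffix(".fid"), sidecar)
    if not bundle.sidecar.exists():
        raise FileNotFoundError(f"sidecar {bundle.sidecar} missing")
    meta = json.loads(bundle.sidecar.read_text())
    version = meta.get("version")
    if version != FORMAT_VERSION:
        raise ValueError(
            f"bundle version {version} != supported {FORMAT_VERSION}; "
            "re-export the FID with this package version"
        )
    params = AcquisitionParams(**meta["params"])
    raw = np.fromfile(bundle.data, dtype="<f8")
    samples = raw[0::2] + 1j * raw[1::2]
    if len(samples) != params.n_points:
        raise ValueError(
            f"{bundle.data}: {len(samples)} stored points != sidecar "
            f"n_points {params.n_points}"
        )
    return FIDRecord(
        samples, params, t_start=meta["t_start"], sample_id=meta["sample_id"],
        provenance=Provenance(meta["provenance"]),
        metadata=dict(meta.get("metadata", {})),
    )


# --- JCAMP-DX (time-domain NTUPLES dialect) --------------------------------

def _norm_label(label: str) -> str:
    return (label.replace(" ", "").replace("-", "").replace("_", "")
            .replace("$", "").replace(".", "").upper())


def write_jcamp(fid: FIDRecord, path: Path | str) -> Path:
    """Write a time-domain JCAMP-DX file (two AFFN pages: real, imaginary)."""
    path = Path(path)
    lines = [
        f"##TITLE= {fid.sample_id or 'fid'}",
        "##JCAMP-DX= 5.00",
        "##DATA TYPE= NMR FID",
        "##DATA CLASS= NTUPLES",
        f"##.OBSERVE FREQUENCY= {fid.params.spectrometer_freq!r}",
        f"##$SWEEP WIDTH= {fid.params.sweep_width!r}",
        f"##$N POINTS= {fid.params.n_points}",
        f"##$CARRIER PPM= {fid.params.carrier_ppm!r}",
        f"##$TEMPERATURE K= {fid.params.temperature_K!r}",
        f"##$T START= {fid.t_start!r}",
        f"##$PROVENANCE= {fid.provenance.value}",
        "##NTUPLES= NMR FID",
    ]
    for page, values in (("1", fid.samples.real), ("2", fid.samples.imag)):
        lines.append(f"##PAGE= N={page}")
        lines.append("##DATA TABLE= (X++(Y..Y)), AFFN")
        for n, v in enumerate(values):
            lines.append(f"{n} {float(v)!r}")
    lines.append("##END NTUPLES= NMR FID")
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_jcamp(path: Path | str) -> FIDRecord:
    """Read a time-domain JCAMP-DX file written in the NTUPLES dialect.

    Required records: observe frequency (MHz), sweep width (Hz) and point
    count; a missing one raises an error naming it. Frequency-domain-only
    files are rejected. Unknown optional records are ignored with a debug
    log message.
    """
    path = Path(path)
    records: dict[str, str] = {}
    pages: list[list[float]] = []
    current: list[float] | None = None
    ended = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = _norm_label(key)
            value = value.strip()
            if key == "PAGE":
                current = []
                pages.append(current)
            elif key == "DATATABLE":
                continue
            elif key == "END" and not value:
                ended = True
            elif key.startswith("END"):
                current = None
            else:
                records[key] = value
        elif current is not None:
            parts = line.split()
            try:
                current.extend(float(p) for p in parts[1:])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad AFFN value") from exc
    if not ended:
        raise ValueError(f"{path}: truncated JCAMP file (no ##END= record)")
    datatype = records.get("DATATYPE", "").upper()
    if "SPECTRUM" in datatype:
        raise ValueError(
            f"{path}: frequency-domain JCAMP file; only time-domain FIDs "
            "are supported"
        )
    required = {
        "OBSERVEFREQUENCY": "observe frequency",
        "SWEEPWIDTH": "sweep width",
        "NPOINTS": "point count",
    }
    for key, human in required.items():
        if key not in records:
            raise ValueError(f"{path}: missing required parameter: {human}")
    n_points = int(float(records["NPOINTS"]))
    if len(pages) != 2:
        raise ValueError(f"{path}: expected 2 data pages (real, imaginary), "
                         f"got {len(pages)}")
    real, imag = (np.asarray(p, dtype=float) for p in pages)
    if len(real) != n_points or len(imag) != n_points:
        raise ValueError(
            f"{path}: header says {n_points} points but pages hold "
            f"{len(real)}/{len(imag)}"
        )
    known = set(required) | {
        "TITLE", "JCAMPDX", "DATATYPE", "DATACLASS", "NTUPLES",
        "CARRIERPPM", "TEMPERATUREK", "TSTART", "PROVENANCE",
    }
    for key in records.keys() - known:
        log.debug("ignoring JCAMP record %s", key)
    params = AcquisitionParams(
        spectrometer_freq=float(records["OBSERVEFREQUENCY"]),
        sweep_width=float(records["SWEEPWIDTH"]),
        n_points=n_points,
        carrier_ppm=float(records.get("CARRIERPPM", 4.7)),
        temperature_K=float(records.get("TEMPERATUREK", 298.2)),
    )
    return FIDRecord(
        real + 1j * imag, params,
        t_start=float(records.get("TSTART", 0.0)),
        sample_id=records.get("TITLE", path.stem),
        provenance=Provenance(records.get("PROVENANCE", "raw")),
    )


# --- amplitude CSVs --------------------------------------------------------

def write_amplitude_csv(table: AmplitudeTable, path: Path | str) -> tuple[Path, Path]:
    """Write the wide CSV to ``path`` and a long-format companion next to it.

    The wide layout has one row per sample and one amplitude column per
    target; the long companion keeps the full per-target detail (ppm, decay,
    phase, component count, residual). Values are written with 12
    significant digits; both files start with a versioned schema comment.
    """
    path = Path(path)
    long_path = path.with_name(path.stem + "_long" + path.suffix)
    wide = table.to_wide()
    with open(path, "w") as fh:
        fh.write(_CSV_HEADER + " (wide)\n")
        wide.to_csv(fh, index=False, float_format="%.12g")
    with open(long_path, "w") as fh:
        fh.write(_CSV_HEADER + " (long)\n")
        table.rows.to_csv(fh, index=False, float_format="%.12g")
    return path, long_path


def read_amplitude_csv(path: Path | str) -> AmplitudeTable:
    """Read a long-format amplitude CSV back into an AmplitudeTable.

    The schema is strict: the versioned header line must match and the
    column set must be exactly the documented one.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith(_CSV_HEADER):
            raise ValueError(
                f"{path}:1: not a fidcraft amplitude table (bad header)"
            )
        if "(long)" not in header:
            raise ValueError(
                f"{path}:1: expected the long-format table; the wide CSV "
                "cannot be read back losslessly"
            )
        try:
            rows = pd.read_csv(fh)
        except Exception as exc:
            raise ValueError(f"{path}: malformed CSV: {exc}") from exc
    unknown = set(rows.columns) - set(TABLE_COLUMNS)
    if unknown:
        raise ValueError(f"{path}: unknown column(s): {sorted(unknown)}")
    missing = set(TABLE_COLUMNS) - set(rows.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s): {sorted(missing)}")
    return AmplitudeTable(rows[TABLE_COLUMNS])
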