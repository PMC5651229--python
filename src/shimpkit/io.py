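"""Readers and writers for per-impulse velocity traces and analysis results.

The vHIT device this method targets exports tests in a proprietary XML
schema that is not publicly documented, so this package defines its own
minimal, open trace formats; an import adapter for a vendor schema can be
added later without touching any analysis code.

CSV dialect (long format). Header comments carry the metadata, then one row
per sample::

    # shimp_test v1
    # test_id=demo
    # protocol=predictable
    # rate_hz=250
    # device=synthetic
    impulse_id,side,sample_index,head_velocity_degps,eye_velocity_degps
    imp0000,right,0,0.0000012,-0.0000011
    ...

``sample_index`` must be contiguous from 0 within each impulse.

XML dialect::

    <shimp_test test_id="demo" protocol="predictable" rate_hz="250" device="synthetic">
      <impulse id="imp0000" side="right">
        <head>0.0000012 0.013 ...</head>
        <eye>-0.0000011 ...</eye>
      </impulse>
    </shimp_test>

A missing ``rate_hz`` attribute defaults to 250 Hz with a logged warning.
Both encodings of the same test parse to equal ``TestFile`` objects. Trace
values are serialized at 10 significant digits, far below every analysis
threshold.

Results are written as a versioned, canonically ordered JSON document
(sorted keys, 2-decimal rounding of deg/s and ms values) so re-serialization
is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .analysis import ImpulseAnalysis, ImpulseRecord, Side
from .errors import IntegrityError, SchemaError
from .peaks import Channel, VelocityTrace
from .summary import TestSummary

__all__ = [
    "TestFile",
    "read_csv_test",
    "write_csv_test",
    "read_xml_test",
    "write_xml_test",
    "write_results_json",
    "read_results_json",
    "RESULTS_SCHEMA_VERSION",
]

logger = logging.getLogger(__name__)

RESULTS_SCHEMA_VERSION = "1"
CSV_COLUMNS = [
    "impulse_id",
    "side",
    "sample_index",
    "head_velocity_degps",
    "eye_velocity_degps",
]
_FLOAT_FMT = "{:.10g}"


@dataclass(frozen=True)
class TestFile:
    """One SHIMP test: metadata plus its list of impulse records."""

    impulses: tuple[ImpulseRecord, ...]
    test_id: str = "unknown"
    protocol: str = "unknown"
    rate_hz: float = 250.0
    device: str = "unknown"

    def __post_init__(self) -> None:
        ids = [imp.impulse_id for imp in self.impulses]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate impulse ids: {dupes}")
        for imp in self.impulses:
            if imp.head.rate_hz != self.rate_hz:
                raise IntegrityError(
                    f"impulse {imp.impulse_id!r} rate {imp.head.rate_hz} Hz "
                    f"differs from test rate {self.rate_hz} Hz"
                )
        object.__setattr__(self, "impulses", tuple(self.impulses))


def _parse_header_comments(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def read_csv_test(path: str | Path, rate_hz: Optional[float] = None) -> TestFile:
    """Read a test from the long-format CSV dialect.

    ``rate_hz`` overrides the ``# rate_hz=`` header comment; without either,
    250 Hz is assumed.
    """
    path = Path(path)
    meta = _parse_header_comments(path)
    if rate_hz is None:
        rate_hz = float(meta.get("rate_hz", 250.0))

    df = pd.read_csv(path, comment="#")
    for col in CSV_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column {col!r}")

    impulses = []
    for impulse_id, grp in df.groupby("impulse_id", sort=False):
        grp = grp.sort_values("sample_index")
        idx = grp["sample_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise IntegrityError(
                f"{path.name}: impulse {impulse_id!r} sample_index is not "
                "contiguous from 0"
            )
        sides = grp["side"].unique()
        side = Side(sides[0]) if len(sides) == 1 else Side.UNKNOWN
        impulses.append(
            ImpulseRecord(
                impulse_id=str(impulse_id),
                side=side,
                head=VelocityTrace(
                    grp["head_velocity_degps"].to_numpy(), rate_hz, Channel.HEAD
                ),
                eye=VelocityTrace(
                    grp["eye_velocity_degps"].to_numpy(), rate_hz, Channel.EYE
                ),
            )
        )
    return TestFile(
        impulses=tuple(impulses),
        test_id=meta.get("test_id", "unknown"),
        protocol=meta.get("protocol", "unknown"),
        rate_hz=rate_hz,
        device=meta.get("device", "unknown"),
    )


def write_csv_test(test: TestFile, path: str | Path) -> None:
    """Write a test in the long-format CSV dialect."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# shimp_test v1\n")
        fh.write(f"# test_id={test.test_id}\n")
        fh.write(f"# protocol={test.protocol}\n")
        fh.write(f"# rate_hz={_FLOAT_FMT.format(test.rate_hz)}\n")
        fh.write(f"# device={test.device}\n")
        fh.write(",".join(CSV_COLUMNS) + "\n")
        for imp in test.impulses:
            for i, (h, e) in enumerate(zip(imp.head.samples, imp.eye.samples)):
                fh.write(
                    f"{imp.impulse_id},{imp.side.value},{i},"
                    f"{_FLOAT_FMT.format(h)},{_FLOAT_FMT.format(e)}\n"
                )


def read_xml_test(path: str | Path, rate_hz: Optional[float] = None) -> TestFile:
    """Read a test from the XML dialect (see module docstring)."""
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        line, col = exc.position
        raise SchemaError(
            f"{path.name}: malformed XML at line {line}, column {col}: {exc.msg}"
        ) from exc
    root = tree.getroot()
    if root.tag != "shimp_test":
        raise SchemaError(f"{path.name}: root element is <{root.tag}>, "
                          "expected <shimp_test>")

    if rate_hz is None:
        if "rate_hz" in root.attrib:
            rate_hz = float(root.attrib["rate_hz"])
        else:
            rate_hz = 250.0
            logger.warning("%s: no rate_hz attribute; assuming 250 Hz", path.name)

    impulses = []
    for el in root.findall("impulse"):
        impulse_id = el.get("id", f"impulse{len(impulses)}")
        head_el, eye_el = el.find("head"), el.find("eye")
        if head_el is None or eye_el is None:
            raise SchemaError(
                f"{path.name}: impulse {impulse_id!r} lacks a <head> or <eye> element"
            )
        head = np.array((head_el.text or "").split(), dtype=float)
        eye = np.array((eye_el.text or "").split(), dtype=float)
        if head.size != eye.size:
            raise IntegrityError(
                f"{path.name}: impulse {impulse_id!r} head ({head.size}) and eye "
                f"({eye.size}) sample counts differ"
            )
        impulses.append(
            ImpulseRecord(
                impulse_id=impulse_id,
                side=Side(el.get("side", "unknown")),
                head=VelocityTrace(head, rate_hz, Channel.HEAD),
                eye=VelocityTrace(eye, rate_hz, Channel.EYE),
            )
        )
    return TestFile(
        impulses=tuple(impulses),
        test_id=root.get("test_id", "unknown"),
        protocol=root.get("protocol", "unknown"),
        rate_hz=rate_hz,
        device=root.get("device", "unknown"),
    )


def write_xml_test(test: TestFile, path: str | Path) -> None:
    """Write a test in the XML dialect."""
    root = ET.Element(
        "shimp_test",
        test_id=test.test_id,
        protocol=test.protocol,
        rate_hz=_FLOAT_FMT.format(test.rate_hz),
        device=test.device,
    )
    for imp in test.impulses:
        el = ET.SubElement(root, "impulse", id=imp.impulse_id, side=imp.side.value)
        ET.SubElement(el, "head").text = " ".join(
            _FLOAT_FMT.format(v) for v in imp.head.samples
        )
        ET.SubElement(el, "eye").text = " ".join(
            _FLOAT_FMT.format(v) for v in imp.eye.samples
        )
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


def _round2(value: Optional[float]) -> Optional[float]:
    return None if value is None else round(float(value), 2)


def _peak_dict(peak) -> Optional[dict]:
    if peak is None:
        return None
    return {
        "index": peak.index,
        "velocity_degps": _round2(peak.velocity),
        "prominence_degps": _round2(peak.prominence),
        "width_samples": _round2(peak.width),
        "left_crossing": _round2(peak.left_crossing),
        "right_crossing": _round2(peak.right_crossing),
        "width_clamped": peak.width_clamped,
    }


def results_document(
    test_summary: TestSummary,
    impulse_analyses: Sequence[ImpulseAnalysis],
    metadata: Optional[dict] = None,
) -> dict:
    """Build the (JSON-serializable) results document."""
    impulses = []
    for a in impulse_analyses:
        sac = None
        if a.saccade is not None:
            sac = {
                "peak": _peak_dict(a.saccade.peak),
                "latency_samples": a.saccade.latency_samples,
                "latency_ms": _round2(a.saccade.latency_ms),
                "width_ms": _round2(a.saccade.width_ms),
                "velocity_degps": _round2(a.saccade.velocity),
                "estp_samples": _round2(a.saccade.estp_samples),
                "early": a.saccade.early,
            }
        impulses.append(
            {
                "impulse_id": a.record_ref,
                "sign": a.sign,
                "head_peak": _peak_dict(a.head_peak),
                "vor_peak": _peak_dict(a.vor_peak),
                "saccade": sac,
                "qc": sorted(a.qc),
            }
        )

    def group(g) -> dict:
        return {
            "n": g.n,
            "latency_mean_ms": _round2(g.latency_mean_ms),
            "latency_sd_ms": _round2(g.latency_sd_ms),
            "width_mean_ms": _round2(g.width_mean_ms),
            "width_sd_ms": _round2(g.width_sd_ms),
            "velocity_mean_degps": _round2(g.velocity_mean),
            "velocity_sd_degps": _round2(g.velocity_sd),
        }

    s = test_summary
    return {
        "schema_version": RESULTS_SCHEMA_VERSION,
        "metadata": dict(metadata or {}),
        "impulses": impulses,
        "summary": {
            "n_impulses": s.n_impulses,
            "rate_hz": s.rate_hz,
            "mean_head_peak_velocity_degps": _round2(s.mean_head_peak_velocity),
            "n_head_below_130": s.n_head_below_130,
            "first_saccade_latency_mean_ms": _round2(s.first_saccade_latency_mean_ms),
            "first_saccade_latency_sd_ms": _round2(s.first_saccade_latency_sd_ms),
            "pct_early": _round2(s.pct_early),
            "early": group(s.early),
            "not_early": group(s.not_early),
            "early_impulse_ids": list(s.early_impulse_ids),
        },
    }


def write_results_json(
    test_summary: TestSummary,
    impulse_analyses: Sequence[ImpulseAnalysis],
    path: str | Path,
    metadata: Optional[dict] = None,
) -> dict:
    """Write the results document; canonical key order, byte-stable."""
    doc = results_document(test_summary, impulse_analyses, metadata)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return doc


def read_results_json(path: str | Path) -> dict:
    """Load a results document written by :func:`write_results_json`."""
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != RESULTS_SCHEMA_VERSION:
        raise SchemaError(
            f"{Path(path).name}: unsupported schema_version "
            f"{doc.get('schema_version')!r}"
        )
    return doc
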