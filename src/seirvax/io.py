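"""Serialization helpers: equilibrium/certificate CSVs and key-value reports.

Numbers are written with ``repr``, the shortest representation that
round-trips to the same double, so downstream comparisons are on values and
never on a fixed decimal format.
"""

from __future__ import annotations

import csv
from typing import Iterable, Sequence

import yaml

from .equilibria import EquilibriumRecord
from .certificates import CertificateReport

__all__ = [
    "equilibria_to_csv",
    "certificate_to_csv",
    "record_to_dict",
    "dump_report",
]


def record_to_dict(rec: EquilibriumRecord) -> dict:
    return {
        "s": rec.location.s,
        "e": rec.location.e,
        "i": rec.location.i,
        "kind": rec.kind,
        "eigenvalues": [str(v) for v in rec.eigenvalues] if rec.eigenvalues else None,
        "max_real_part": rec.max_real_part,
        "label": rec.label,
        "feasible": rec.feasible,
        "residual": rec.residual,
    }


def equilibria_to_csv(records: Iterable[EquilibriumRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["s", "e", "i", "max_real_part", "label", "feasible"])
        for rec in records:
            w.writerow(
                [
                    repr(rec.location.s),
                    repr(rec.location.e),
                    repr(rec.location.i),
                    repr(rec.max_real_part) if rec.max_real_part is not None else "",
                    rec.label or "",
                    rec.feasible,
                ]
            )


def certificate_to_csv(report: CertificateReport, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        if report.kind == "lozinskii":
            w.writerow(["t", "g1", "g2", "e_log_derivative"])
            for t, g1, g2, eoe in zip(report.times, report.g1, report.g2, report.e_log_derivative):
                w.writerow([repr(float(t)), repr(float(g1)), repr(float(g2)), repr(float(eoe))])
        else:
            w.writerow(["t", "L"])
            for t, v in zip(report.times, report.values):
                w.writerow([repr(float(t)), repr(float(v))])


def dump_report(doc: dict, stream=None) -> str:
    """Serialize a report dict as a key-value YAML document."""
    text = yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)
    if stream is not None:
        stream.write(text)
    return text
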