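"""Result serialization: deterministic file layout with a checksum manifest.

Two runs with the same seed and config produce byte-identical result files
(the run log deliberately carries no wall-clock timestamps), so the
manifest checksums double as a reproducibility check.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__ as _version

__all__ = ["write_results", "verify_manifest", "design_to_csv", "moments_to_csv"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def design_to_csv(design, path: Path) -> None:
    """Write a stimulus design as segment table: start, end, amplitude."""
    edges = design.segment_edges()
    amps = design.segment_amplitudes()
    lines = ["segment_start,segment_end,amplitude"]
    for s, e, a in zip(edges[:-1], edges[1:], amps):
        lines.append(f"{s:.10g},{e:.10g},{a:.10g}")
    path.write_text("\n".join(lines) + "\n")


def moments_to_csv(moments, path: Path) -> None:
    """Write a MomentTrajectory in long format (time, i, j, mean_i, cov_ij)."""
    moments.to_frame().to_csv(path, index=False, float_format="%.12g")


def _default_json(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_results(bundle: dict, out_dir: str | Path) -> dict:
    """Write a result bundle and return the manifest.

    Recognized bundle keys (all optional): ``config_echo`` (str),
    ``design`` (StimulusDesign), ``moments`` (dict name -> MomentTrajectory),
    ``report`` (dict or object with to_dict), ``log`` (list of str lines).
    The manifest lists every file with its sha256 checksum and is itself
    written as ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    config_echo = bundle.get("config_echo", "")
    p = out / "config_echo.yaml"
    p.write_text(config_echo)
    files.append(p)

    if "design" in bundle and bundle["design"] is not None:
        p = out / "design.csv"
        design_to_csv(bundle["design"], p)
        files.append(p)

    for name, moments in (bundle.get("moments") or {}).items():
        p = out / f"moments_{name}.csv"
        moments_to_csv(moments, p)
        files.append(p)

    report = bundle.get("report")
    if report is not None:
        if hasattr(report, "to_dict"):
            report = report.to_dict()
        p = out / "report.json"
        p.write_text(json.dumps(report, indent=2, sort_keys=True,
                                default=_default_json) + "\n")
        files.append(p)

    log_lines = [f"roed version {_version}"] + list(bundle.get("log", []))
    p = out / "run.log"
    p.write_text("\n".join(log_lines) + "\n")
    files.append(p)

    manifest = {"version": _version,
                "files": {f.name: _sha256(f) for f in files}}
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def verify_manifest(out_dir: str | Path) -> dict[str, bool]:
    """Re-hash the files listed in a manifest; True = intact."""
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    return {name: (out / name).exists() and _sha256(out / name) == digest
            for name, digest in manifest["files"].items()}
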