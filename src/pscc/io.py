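"""Readers/writers for the on-disk formats.

Windows travel as BED4 (chrom, start, end, n_sim) with a metadata header;
counts, panels, RCR tracks and segments as TSV; calls as BED6+ and as
VCF 4.2 with symbolic <DEL>/<DUP> ALTs.  All coordinates are 0-based
half-open except VCF POS (1-based, per the standard).  Every writer puts
the tool version and the relevant parameters in a ``#`` header so outputs
are self-describing, and windows files carry a checksum that counts and
panel files repeat, so mismatched inputs are caught at load time.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .calling import CnvCall
from .correction import ControlPanel
from .windows import ReadCountTrack


class FormatError(ValueError):
    """Malformed input file; carries the offending line number."""

    def __init__(self, path, lineno, message):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def windows_checksum(windows: pd.DataFrame) -> str:
    h = hashlib.sha256()
    for row in windows.itertuples(index=False):
        h.update(f"{row.chrom}\t{row.start}\t{row.end}\n".encode())
    return h.hexdigest()[:16]


def _header(kind: str, meta: dict) -> str:
    fields = " ".join(f"{k}={v}" for k, v in meta.items())
    return f"#pscc {kind} version={_version} {fields}\n"


def _read_meta(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tok in line.rstrip("\n").split()[1:]:
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
    return meta


def write_windows_bed(windows: pd.DataFrame, path) -> None:
    meta = {
        k: windows.attrs.get(k, "NA")
        for k in ("expected_rc", "read_length", "u_sim", "n_w")
    }
    meta["checksum"] = windows_checksum(windows)
    with open(path, "w") as fh:
        fh.write(_header("windows", meta))
        for row in windows.itertuples(index=False):
            flag = "\tpartial" if row.partial else ""
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.n_sim}{flag}\n")


def read_windows_bed(path) -> pd.DataFrame:
    meta = _read_meta(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise FormatError(path, lineno, "expected >= 4 BED columns")
            try:
                rows.append(
                    (
                        parts[0],
                        int(parts[1]),
                        int(parts[2]),
                        int(parts[3]),
                        len(parts) > 4 and parts[4] == "partial",
                    )
                )
            except ValueError as e:
                raise FormatError(path, lineno, str(e)) from None
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_sim", "partial"])
    for k in ("expected_rc", "read_length", "u_sim", "n_w"):
        if meta.get(k, "NA") != "NA":
            df.attrs[k] = int(meta[k])
    return df


def write_counts_tsv(track: ReadCountTrack, windows: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            _header(
                "counts",
                {"sample": track.sample, "checksum": windows_checksum(windows)},
            )
        )
        fh.write("window_index\tchrom\tstart\tend\tcount\tgc\tusable\n")
        for i, row in enumerate(windows.itertuples(index=False)):
            fh.write(
                f"{i}\t{row.chrom}\t{row.start}\t{row.end}\t"
                f"{track.counts[i]:.6g}\t{track.gc[i]:.6g}\t{int(track.usable[i])}\n"
            )


def read_counts_tsv(path, windows: pd.DataFrame | None = None) -> ReadCountTrack:
    meta = _read_meta(path)
    if windows is not None:
        want = windows_checksum(windows)
        if meta.get("checksum") not in (None, want):
            raise ValueError(
                f"{path}: counts were made against different windows "
                f"(checksum {meta.get('checksum')} != {want})"
            )
    df = pd.read_csv(path, sep="\t", comment="#")
    return ReadCountTrack(
        sample=meta.get("sample", Path(str(path)).stem),
        counts=df["count"].to_numpy(),
        gc=df["gc"].to_numpy(),
        usable=df["usable"].to_numpy().astype(bool),
    )


def counts_windows(path) -> pd.DataFrame:
    """Recover the window table embedded in a counts TSV."""
    df = pd.read_csv(path, sep="\t", comment="#")
    w = df[["chrom", "start", "end"]].copy()
    w["n_sim"] = 0
    w["partial"] = ~df["usable"].astype(bool)
    return w


def write_panel_tsv(panel: ControlPanel, windows: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            _header(
                "panel",
                {
                    "n_controls": panel.n_controls,
                    "target_median": f"{panel.target_median:.6g}",
                    "checksum": windows_checksum(windows),
                },
            )
        )
        fh.write("window_index\tmu\tsigma\tusable\n")
        for i in range(len(panel.mu)):
            fh.write(
                f"{i}\t{panel.mu[i]:.6g}\t{panel.sigma[i]:.6g}\t{int(panel.usable[i])}\n"
            )


def read_panel_tsv(path, windows: pd.DataFrame | None = None) -> ControlPanel:
    meta = _read_meta(path)
    if windows is not None:
        want = windows_checksum(windows)
        if meta.get("checksum") not in (None, want):
            raise ValueError(
                f"{path}: panel was built against different windows "
                f"(checksum {meta.get('checksum')} != {want})"
            )
    df = pd.read_csv(path, sep="\t", comment="#")
    return ControlPanel(
        mu=df["mu"].to_numpy(),
        sigma=df["sigma"].to_numpy(),
        usable=df["usable"].to_numpy().astype(bool),
        n_controls=int(meta.get("n_controls", 2)),
        target_median=float(meta.get("target_median", "nan")),
    )


def write_segments_tsv(segments: pd.DataFrame, windows: pd.DataFrame, path) -> None:
    start = windows["start"].to_numpy()
    end = windows["end"].to_numpy()
    with open(path, "w") as fh:
        fh.write(_header("segments", {"checksum": windows_checksum(windows)}))
        fh.write("chrom\tstart\tend\tn_windows\tmean_rcr\n")
        for row in segments.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{start[row.first_win]}\t{end[row.last_win]}\t"
                f"{row.n_windows}\t{row.mean_rcr:.6g}\n"
            )


def write_calls_bed(calls: list[CnvCall], path, params: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header("calls", params or {}))
        fh.write(
            "#chrom\tstart\tend\tstate\tcopy_number\tstrand\t"
            "mean_rcr\tn_windows\tst_p\tpt_p\tsample\n"
        )
        for c in sorted(calls, key=lambda c: (c.chrom, c.start)):
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.state}\t{c.copy_number}\t.\t"
                f"{c.mean_rcr:.4f}\t{c.n_windows}\t{c.st_p:.3g}\t{c.pt_p:.3g}\t{c.sample}\n"
            )


def read_calls_bed(path) -> list[CnvCall]:
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            p = line.rstrip("\n").split("\t")
            if len(p) < 11:
                raise FormatError(path, lineno, "expected 11 columns")
            calls.append(
                CnvCall(
                    chrom=p[0],
                    start=int(p[1]),
                    end=int(p[2]),
                    state=p[3],
                    copy_number=int(p[4]),
                    mean_rcr=float(p[6]),
                    n_windows=int(p[7]),
                    st_p=float(p[8]),
                    pt_p=float(p[9]),
                    sample=p[10],
                )
            )
    return calls


def write_calls_vcf(
    calls: list[CnvCall], path, contigs: dict[str, int] | None = None
) -> None:
    """VCF 4.2 with symbolic ALTs, END/SVLEN/SVTYPE INFO and a CN FORMAT."""
    sample = calls[0].sample if calls else "sample"
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=pscc-{_version}",
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=DUP,Description="Duplication">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
        '##FORMAT=<ID=CN,Number=1,Type=Integer,Description="Copy number">',
    ]
    if contigs:
        for name, length in contigs.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    for k, c in enumerate(sorted(calls, key=lambda c: (c.chrom, c.start)), 1):
        svtype = "DEL" if c.state == "deletion" else "DUP"
        svlen = c.size if svtype == "DUP" else -c.size
        lines.append(
            f"{c.chrom}\t{c.start + 1}\tpscc{k}\tN\t<{svtype}>\t.\tPASS\t"
            f"END={c.end};SVTYPE={svtype};SVLEN={svlen}\tCN\t{c.copy_number}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_manifest(path, params: dict, inputs: dict[str, str], seed=None) -> None:
    """Reproducibility manifest: parameters, input checksums, seed."""
    Path(path).write_text(
        json.dumps(
            {"version": _version, "seed": seed, "params": params, "inputs": inputs},
            indent=2,
            sort_keys=True,
            default=str,
        )
        + "\n"
    )


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
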