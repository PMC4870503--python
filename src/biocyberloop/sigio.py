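"""Plain-text readers/writers for signals, scripts and analysis tables.

Native signal format: a header line ``# fs=<Hz> channels=<a,b> units=uV``
followed by one tab-separated row per sample (time with 6 decimals, then one
microvolt value per channel with 4 decimals).  The ground-truth sidecar holds
one row per script segment.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import EEGRecording, Segment, StateScript

__all__ = [
    "write_recording",
    "read_recording",
    "write_sidecar",
    "read_sidecar",
    "write_band_power_table",
]


def write_recording(recording: EEGRecording, path: str | Path) -> None:
    path = Path(path)
    t = recording.start_time + np.arange(recording.n_samples) / recording.sampling_rate
    header = (
        f"# fs={recording.sampling_rate:g} "
        f"channels={','.join(recording.channel_labels)} units=uV\n"
    )
    buf = io.StringIO()
    data = np.column_stack([t] + list(recording.samples))
    np.savetxt(buf, data, fmt=["%.6f"] + ["%.4f"] * len(recording.channel_labels),
               delimiter="\t")
    path.write_text(header + buf.getvalue())


def read_recording(path: str | Path) -> EEGRecording:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
    if not header.startswith("#"):
        raise ValueError(f"{path}: missing '# fs=... channels=...' header")
    fields = dict(item.split("=", 1) for item in header[1:].split() if "=" in item)
    fs = float(fields["fs"])
    labels = fields["channels"].split(",")
    data = np.loadtxt(path, skiprows=1, delimiter="\t")
    data = np.atleast_2d(data)
    return EEGRecording(fs, labels, data[:, 1:].T, start_time=float(data[0, 0]))


def write_sidecar(script: StateScript, path: str | Path) -> None:
    """One row per segment: start_s  end_s  state  theta_mult  alpha_mult."""
    edges = script.boundaries()
    rows = ["start_s\tend_s\tstate\ttheta_mult\talpha_mult"]
    for seg, t0, t1 in zip(script.segments, edges[:-1], edges[1:]):
        rows.append(
            f"{t0:.3f}\t{t1:.3f}\t{seg.state}\t"
            f"{seg.theta_multiplier:.6g}\t{seg.alpha_multiplier:.6g}"
        )
    Path(path).write_text("\n".join(rows) + "\n")


def read_sidecar(path: str | Path) -> StateScript:
    df = pd.read_csv(path, sep="\t")
    segments = tuple(
        Segment(float(r.end_s) - float(r.start_s), str(r.state),
                float(r.theta_mult), float(r.alpha_mult))
        for r in df.itertuples()
    )
    return StateScript(segments)


def write_band_power_table(series_list, path: str | Path) -> None:
    """Tab-separated export: time_s  channel  band  power_uV2  log_power  artifact."""
    frames = []
    for s in series_list:
        frames.append(pd.DataFrame({
            "time_s": s.times,
            "channel": s.channel,
            "band": s.band.name,
            "power_uV2": s.power,
            "log_power": s.log_power,
            "artifact": s.artifact_flags.astype(int),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False,
                                                float_format="%.6g")
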