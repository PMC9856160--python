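#!/usr/bin/env python
"""Detect sharp-wave ripples, measure them, and contrast their density.

Detection on the pyramidal-layer channel (3.5 SD envelope threshold,
1 SD onset/offset, 50 ms refractory), 7-cycle Morlet per-event metrics,
peri-stimulus density in 5-s bins, and CA1 layer assignment from the
ripple-triggered laminar profile.  Writes results/events.csv and
results/layers.csv.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from optotheta import ripples, synchrony
from optotheta.io_model import read_protocol, read_recording

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--session", type=Path, default=ROOT / "results" / "session")
    args = ap.parse_args()
    rec = read_recording(args.session / "lfp.dat")
    protocol = read_protocol(args.session / "protocol.csv",
                             session_length=rec.duration)
    hp = rec.by_region("HP")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        events = ripples.detect_ripples(
            rec.channel_data(hp[len(hp) // 2].id), rec.rate)
        prof, lags, band_rms = ripples.ripple_triggered_profile(
            rec=rec, events=events, return_band_rms=True)
        layers = synchrony.assign_layers(prof, lags, rec, band_rms=band_rms)
        chan = next(c for c, l in layers.items() if l == "pyramidale")
        events = ripples.detect_ripples(rec.channel_data(chan), rec.rate,
                                        channel_id=chan)
        events = ripples.ripple_metrics(events, rec.channel_data(chan),
                                        rec.rate)
        density = ripples.ripple_density(events, protocol)
    out = ROOT / "results"
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([{
        "onset_s": e.onset, "end_s": e.end, "peak_time_s": e.peak_time,
        "duration_ms": e.duration, "peak_freq_hz": e.peak_freq,
        "amplitude_z": e.amplitude, "channel_id": e.channel_id}
        for e in events]).to_csv(out / "events.csv", index=False,
                                 float_format="%.4f")
    pd.DataFrame([{"channel_id": c, "layer": l}
                  for c, l in layers.items()]).to_csv(
        out / "layers.csv", index=False)
    df = pd.read_csv(out / "events.csv")
    print(f"{len(events)} ripples on pyramidale channel {chan}: "
          f"{df.duration_ms.mean():.0f} ms, {df.peak_freq_hz.mean():.0f} Hz, "
          f"{df.amplitude_z.mean():.1f} z on average")
    print(f"density off {density['off_rate']:.3f}/s -> on "
          f"{density['on_rate']:.3f}/s ({100 * density['contrast']:+.1f}%)")
    print(f"layers: {layers}")
    print(f"wrote {out / 'events.csv'} and {out / 'layers.csv'}")


if __name__ == "__main__":
    main()
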