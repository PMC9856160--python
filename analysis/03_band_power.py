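#!/usr/bin/env python
"""Per-band LFP power contrast between light-off and light-on epochs.

Multitaper spectra (TW = 3, 5 tapers, one 5-s window per epoch) on the
pyramidal-layer channel, paired per trial, Lilliefors-gated paired
t/Wilcoxon tests with Benjamini-Hochberg correction across bands.
Writes results/band_table.csv.
"""

import argparse
import warnings
from pathlib import Path

from optotheta import dsp, ripples, spectral, synchrony
from optotheta.io_model import paired_epochs, read_protocol, read_recording

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--session", type=Path, default=ROOT / "results" / "session")
    args = ap.parse_args()
    rec = read_recording(args.session / "lfp.dat")
    protocol = read_protocol(args.session / "protocol.csv",
                             session_length=rec.duration)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hp = rec.by_region("HP")
        mid = hp[len(hp) // 2].id
        events = ripples.detect_ripples(rec.channel_data(mid), rec.rate)
        chan = synchrony.pyramidale_channel(rec, events)
        x = dsp.resample(rec.channel_data(chan), rec.rate, 500.0)
        off_p, on_p = spectral.per_trial_band_powers(
            x, 500.0, paired_epochs(protocol))
        table = spectral.compare_bands(off_p, on_p)
    df = table.to_frame()
    out = ROOT / "results" / "band_table.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out, index=False, float_format="%.6g")
    theta = table["theta"]
    print(f"pyramidale channel: {chan}")
    for r in df.itertuples():
        star = " (*)" if r.significant else ""
        print(f"  {r.band:11s} off {r.mean_off:9.1f}  on {r.mean_on:9.1f} "
              f" p_fdr {r.p_fdr:.3g}{star}")
    print(f"theta change: {100 * (theta['mean_on'] / theta['mean_off'] - 1):+.1f}%")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
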