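#!/usr/bin/env python
"""Simulate one default optogenetic session and write it to disk.

Produces results/session/{lfp.dat,lfp.json,spikes.csv,protocol.csv}: a
10-minute recording (8 CA1 channels spanning oriens-radiatum, 2 septal
channels), 80 sorted units, and the 15 s off / 5 s on light protocol.
"""

import argparse
from pathlib import Path

from optotheta import synth

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "session")
    args = ap.parse_args()
    cfg = synth.SynthConfig(seed=args.seed)
    rec, spikes, protocol = synth.generate_session(cfg, out_dir=args.out)
    gt = rec.ground_truth
    print(f"session {rec.session_id}: {rec.n_channels} channels x "
          f"{rec.duration:.0f} s at {rec.rate:.0f} Hz")
    print(f"  {len(spikes)} units, {protocol.onsets.size} light pulses, "
          f"{gt.ripple_times.size} injected ripple events")
    print(f"  written to {args.out}")


if __name__ == "__main__":
    main()
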