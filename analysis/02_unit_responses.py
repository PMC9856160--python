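#!/usr/bin/env python
"""Classify every unit's response to septal light pulses.

Sliding-sweeps templates (+/-15 s, 500 ms bins) around each pulse are
tested against 1000 interval-shuffle surrogates; units outside the 95%
null band are excited/inhibited.  Writes results/units_summary.csv and
prints the per-region population summary (fractions modulated, mean
effects, global rate change).
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from optotheta import unit_response
from optotheta.io_model import read_protocol, read_spikes

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--session", type=Path, default=ROOT / "results" / "session")
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    spikes = read_spikes(args.session / "spikes.csv")
    protocol = read_protocol(args.session / "protocol.csv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cls = unit_response.classify_all(spikes, protocol, seed=args.seed)
    region_of = {uid: r for uid, r, _ in spikes}
    rows = [{"unit_id": c.unit_id, "region": region_of[c.unit_id],
             "label": c.label, "effect_pct": c.effect_pct,
             "p_like": c.p_like, "off_rate_hz": c.off_rate,
             "on_rate_hz": c.on_rate} for c in cls]
    out = ROOT / "results" / "units_summary.csv"
    out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(out, index=False, float_format="%.4f")
    for region in ("MS", "HP"):
        sub = [c for c in cls if region_of[c.unit_id] == region]
        s = unit_response.population_summary(sub)
        print(f"{region}: {100 * s['frac_excited']:.1f}% excited "
              f"({s['excited_effect_mean_pct']:+.1f} +/- "
              f"{s['excited_effect_sem_pct']:.1f}%), "
              f"{100 * s['frac_inhibited']:.1f}% inhibited "
              f"({s['inhibited_effect_mean_pct']:+.1f}%), "
              f"global rate change {s['global_rate_change_pct']:+.1f}%")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
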