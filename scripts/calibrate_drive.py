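"""Drive-calibration sweep for the desk-scale network.

Reproduces the procedure used to fix the default background-drive peak
conductance (NetworkConfig.drive_gmax_s): scan candidate values, simulate
the undamaged network and the 50% whole-cell condition, and report the
aggregate firing rates.  The default was chosen so that the undamaged
2-microcolumn patch fires at the Table-1-like scale of tens of APs/s
while 50% whole-cell damage silences it.

Usage:  python scripts/calibrate_drive.py [--seed 1234] [--duration 5]
"""

import argparse

from cortexdamage.damage_model import DamageSpec, apply_damage
from cortexdamage.engine import Simulation
from cortexdamage.network_builder import build_network, desk_scale_config


def rate(cfg, level, location, duration):
    net = build_network(cfg)
    if level > 0:
        net = apply_damage(net, DamageSpec(level, location))
    rec = Simulation(net).run(duration, record_soma=False)
    return len(rec.spikes) / duration


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1234)
    ap.add_argument("--duration", type=float, default=5.0)
    ap.add_argument("--candidates", default="6e-9,8e-9,10e-9,12e-9")
    args = ap.parse_args()
    print(f"{'drive gmax (nS)':>16s} {'baseline APs/s':>15s} {'50% whole APs/s':>16s}")
    for g in (float(s) for s in args.candidates.split(",")):
        cfg = desk_scale_config(seed=args.seed, drive_gmax_s=g)
        r0 = rate(cfg, 0.0, "whole_cell", args.duration)
        r5 = rate(cfg, 0.5, "whole_cell", args.duration)
        print(f"{g * 1e9:16.1f} {r0:15.1f} {r5:16.1f}")


if __name__ == "__main__":
    main()
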