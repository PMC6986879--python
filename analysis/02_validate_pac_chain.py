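#!/usr/bin/env python
"""Validate the PAC/PRP chain on the two-oscillation simulation.

An 8 Hz cosine plus a 40 Hz cosine is analyzed twice: with constant
40 Hz amplitude (no coupling) and with 40 Hz gaussian bursts (FWHM half
a slow cycle) at 180 degrees of the slow cycle.  The uncoupled signal
should give a modulation index near zero and equal peak/trough
phase-referenced power; the coupled signal should give MI about two
orders of magnitude larger, the peak recovered at 180 degrees, and peak
PRP well above trough PRP.
"""

from pathlib import Path

from prpdecode import reproduce_simulation_figure

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    report = reproduce_simulation_figure(ROOT / "results")
    none, burst = report["none"], report["burst"]
    print(f"uncoupled: MI = {none['mi']:.2e}, "
          f"peak-trough PRP = {none['prp_peak_minus_trough_db']:+.2f} dB")
    print(f"coupled:   MI = {burst['mi']:.2e}, "
          f"peak at {burst['peak_phase_deg']:.0f} deg, "
          f"peak-trough PRP = {burst['prp_peak_minus_trough_db']:+.2f} dB")
    print(f"MI ratio coupled/uncoupled = {burst['mi'] / none['mi']:.0f}x")
    print(f"wrote {ROOT / 'results' / 'simulation_report.csv'}")


if __name__ == "__main__":
    main()
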