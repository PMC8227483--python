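"""Generate the packaged synthetic x-ray spectra and bowtie profiles.

The measured 80/100 kV spectra and Al-equivalent bowtie profiles of the
dual-source scanner modelled by this package are not publicly available, so
the package ships synthetic stand-ins:

* spectra: Kramers-type tungsten bremsstrahlung N(E) ~ (E0 - E)/E filtered by
  6.5 mm of aluminium (a typical CT inherent filtration, consistent with
  published 80 kV CT half-value layers of ~6 mm Al), plus tungsten K
  fluorescence lines (58.0, 59.3, 67.2, 69.1 keV) for tube voltages above the
  K edge with relative strength 0.35 * (E0/69.5 - 1)^1.67 of the filtered
  continuum;
* bowtie profiles: smooth even polynomials in fan angle with zero added
  thickness at the centre; they represent Al-equivalent thickness *in
  addition to* the inherent filtration already folded into the spectra.

Outputs are two-column whitespace text files under src/perfdose/data/ with
"_synthetic" in the name to mark them as stand-ins.
"""

from __future__ import annotations

import numpy as np
from pathlib import Path

DATA = Path(__file__).resolve().parents[1] / "src" / "perfdose" / "data"
RHO_AL = 2.699  # g/cm^3
INHERENT_MM_AL = 6.5
W_K_EDGE = 69.5
W_LINES = {58.0: 0.31, 59.3: 0.57, 67.2: 0.08, 69.1: 0.04}  # relative intensities


def load_al_mu() -> tuple[np.ndarray, np.ndarray]:
    rows = []
    with (DATA / "element_coefficients.tsv").open() as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("element"):
                continue
            el, _, _, e, mu, _ = line.split("\t")
            if el == "Al":
                rows.append((float(e), float(mu)))
    arr = np.array(sorted(rows))
    return arr[:, 0], arr[:, 1]


def mu_al(e_kev: np.ndarray) -> np.ndarray:
    eg, mg = load_al_mu()
    return np.exp(np.interp(np.log(e_kev), np.log(eg), np.log(mg)))


def spectrum(kv: int) -> tuple[np.ndarray, np.ndarray]:
    e = np.arange(1.0, kv + 1.0)
    n = np.clip((kv - e), 0.0, None) / e
    n *= np.exp(-mu_al(e) * RHO_AL * INHERENT_MM_AL / 10.0)
    if kv > W_K_EDGE:
        strength = 0.35 * (kv / W_K_EDGE - 1.0) ** 1.67 * n.sum()
        total_rel = sum(W_LINES.values())
        for el, rel in W_LINES.items():
            idx = int(round(el)) - 1
            n[idx] += strength * rel / total_rel
    n /= n.sum()
    return e, n


def bowtie(tube: str) -> tuple[np.ndarray, np.ndarray]:
    # half fan angles: tube A 0.7955/2 rad, tube B 0.5441/2 rad
    half = 0.7955 / 2 if tube == "A" else 0.5441 / 2
    theta = np.linspace(-half, half, 81)
    if tube == "A":
        t = 50.0 * theta**2 + 390.0 * theta**4
    else:
        t = 65.0 * theta**2 + 500.0 * theta**4
    return theta, t


def main() -> None:
    for kv in (80, 100):
        e, n = spectrum(kv)
        out = DATA / f"spectrum_{kv}kv_synthetic.txt"
        with out.open("w") as fh:
            fh.write(f"# Synthetic {kv} kV tungsten spectrum (see scripts/make_spectra.py)\n")
            fh.write("# energy_keV relative_fluence\n")
            for ei, ni in zip(e, n):
                fh.write(f"{ei:.1f} {ni:.8e}\n")
        mean = (e * n).sum()
        print(f"{out.name}: mean energy {mean:.2f} keV")
    for tube in ("A", "B"):
        theta, t = bowtie(tube)
        out = DATA / f"bowtie_tube{tube}_80kv_synthetic.txt"
        with out.open("w") as fh:
            fh.write(f"# Synthetic Al-equivalent bowtie profile, tube {tube} "
                     "(additional to inherent filtration; see scripts/make_spectra.py)\n")
            fh.write("# fan_angle_rad thickness_mm_Al\n")
            for th, ti in zip(theta, t):
                fh.write(f"{th:.6f} {ti:.6f}\n")
        print(f"{out.name}: centre {t[len(t)//2]:.2f} mm, edge {t[0]:.2f} mm")


if __name__ == "__main__":
    main()
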