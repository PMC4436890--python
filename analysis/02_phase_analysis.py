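"""Phase recovery and comparison of the two delay-cancellation routes.

On noiseless data both routes recover the stimulus phase exactly (after
the documented time-reversal offset correction) and the delay map is
spatially constant at the injected hemodynamic delay.  Under noise the
reverse-average route is noisier per voxel — its signal amplitude is
attenuated by cos(phi_h - C/2) — but after the 2.5 mm surface
smoothing both chains apply, their maps agree closely.  Writes
results/route_agreement.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from retmap import coding, phase, surface, synth, wrap_phase
from retmap.types import StimulusParams


def main(seed: int, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    stim = StimulusParams()
    mesh = synth.build_flat_patch(60.0, 62.0, 1.0)
    vf, _ = synth.synthesize_ground_truth(mesh, None, stim)
    smoother = surface.SurfaceSmoother(mesh, 2.5)

    def routes(runs, coord):
        fwd, bwd = runs[(coord, "forward")], runs[(coord, "backward")]
        mf, mb = phase.dft_phase_snr(fwd), phase.dft_phase_snr(bwd)
        m1, delay = phase.combine_opposite_directions(mf, mb, stim.period_s)
        comb, off = phase.reverse_average_combine(fwd, bwd)
        mc = phase.dft_phase_snr(comb)
        p2 = phase.stimulus_phase_from_reverse_average(mc, off)
        return m1, delay, p2

    runs = synth.simulate_runs(vf, stim, seed=seed)
    m1, delay, p2 = routes(runs, "eccentricity")
    truth_phi = wrap_phase(coding.eccentricity_to_phase(vf.eccentricity, stim))
    ok = vf.valid
    print(f"noiseless phase recovery: max error "
          f"{np.max(np.abs(wrap_phase(m1.phase[ok] - truth_phi[ok]))):.2e} rad")
    print(f"recovered delay: {np.mean(delay[ok]):.6f} s "
          f"(spread {np.ptp(delay[ok]):.2e} s; injected {stim.hemo_delay_s} s)")
    print(f"noiseless route disagreement (raw): "
          f"{np.max(np.abs(wrap_phase(m1.phase[ok] - p2[ok]))):.2e} rad")

    rows = []
    for target_snr in (10.0, 3.0, 1.5):
        sd = synth.noise_sd_for_snr(target_snr, 1.0, stim)
        raw_meds, sm_meds = [], []
        for rep in range(20):
            r = synth.simulate_runs(vf, stim, noise_sd=sd, seed=seed + 100 + rep)
            m1, _, p2 = routes(r, "eccentricity")
            raw_meds.append(np.nanmedian(np.abs(wrap_phase(m1.phase - p2))))
            import dataclasses

            mc_like = dataclasses.replace(m1, phase=p2)
            s1, s2 = smoother.smooth_map(m1), smoother.smooth_map(mc_like)
            sm_meds.append(np.nanmedian(np.abs(wrap_phase(s1.phase - s2.phase))))
        rows.append({
            "target_snr": target_snr,
            "noise_sd": round(sd, 3),
            "raw_median_disagreement_rad": round(float(np.median(raw_meds)), 4),
            "smoothed_median_disagreement_rad": round(float(np.median(sm_meds)), 4),
        })
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "route_agreement.tsv", sep="\t", index=False)
    print("\nroute disagreement by noise level (median over vertices, 20 reps):")
    print(table.to_string(index=False))


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    a = ap.parse_args()
    main(a.seed, a.out)
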