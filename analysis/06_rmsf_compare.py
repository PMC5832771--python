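#!/usr/bin/env python
"""Bound-versus-apo Cα fluctuation comparison.

The independent mobility check on the rigidification story: apo receptor
runs are generated with elevated positional noise in the second-helix
region (emulating segments that are mobile without the peptide), bound
runs with baseline noise. The per-residue RMSF difference (apo - bound)
should be positive exactly where the extra mobility was planted.
"""

from pathlib import Path

import peptisite as ps

OUT = "results"
MOBILE_RANGE = range(158, 164)      # helix-2 segment mobile without peptide
EXTRA_NOISE = 3.0                   # x baseline jitter


def main():
    Path(OUT).mkdir(exist_ok=True)
    dimer = ps.build_toy_dimer()
    scale = {(c, r): EXTRA_NOISE for c in "AB" for r in MOBILE_RANGE}
    bound = ps.simulate_apo_runs(dimer, n_runs=5, frames_per_run=200, seed=21)
    apo = ps.simulate_apo_runs(dimer, n_runs=5, frames_per_run=200, seed=22,
                               residue_noise_scale=scale)
    table = ps.rmsf_compare(bound, apo)
    table.to_csv(f"{OUT}/rmsf_compare.tsv", sep="\t", index=False)

    mobile = table[table.res_seq.isin(MOBILE_RANGE)]
    rest = table[~table.res_seq.isin(MOBILE_RANGE)]
    print(f"planted mobile segment {min(MOBILE_RANGE)}-{max(MOBILE_RANGE)}: "
          f"mean ΔRMSF (apo - bound) = {mobile.delta.mean():.2f} Å "
          f"(max {mobile.delta.max():.2f} Å)")
    print(f"remaining residues: mean ΔRMSF = {rest.delta.mean():.3f} Å")
    print(f"wrote {OUT}/rmsf_compare.tsv")


if __name__ == "__main__":
    main()
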