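#!/usr/bin/env python
"""Generate the synthetic structure ensemble the analysis runs on.

Builds one C4-symmetric closed-state tetramer (folded linkers, narrow
anchor rings) and six open-state tetramers (unfolded linkers, wide rings,
tumbling gating ring; one structure with a folded linker and a stretched
neighbour), each in a random rigid pose.  Writes Cα-only PDB files plus a
ground-truth sidecar under scratch/structures/.
"""

import json
import sys
from pathlib import Path

from wlcgating import closed_state_fixture, open_state_ensemble, write_fixture_pdb
from wlcgating.synthetic import _calibrate_open_ensemble

OUTDIR = Path(__file__).resolve().parents[1] / "scratch" / "structures"
SEED = 20230703


def main() -> None:
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else SEED
    offset, depth, tilts, outlier_tilt = _calibrate_open_ensemble()
    print("calibrated open-state geometry:")
    print(f"  ring azimuthal offset : {offset:.2f} deg")
    print(f"  ring depth            : {depth:.2f} A below the pore anchors")
    print(f"  ring tilts            : "
          + ", ".join(f"{t:.1f}" for t, _ in tilts) + " deg (dome pivot)")
    print(f"  outlier-structure tilt: {outlier_tilt:.1f} deg (ring-center pivot)")

    closed, closed_truth = closed_state_fixture()
    opens, truths = open_state_ensemble(seed=seed)
    truths[closed.id] = closed_truth
    OUTDIR.mkdir(parents=True, exist_ok=True)
    for model in [closed] + opens:
        path = write_fixture_pdb(model, OUTDIR / f"{model.id}.pdb")
        print(f"  wrote {path.name}")
    sidecar = {sid: {"per_chain": {c: [round(x, 4) for x in v]
                                   for c, v in t.per_chain.items()},
                     "tilt_deg": round(t.tilt_deg, 3),
                     "folded_chains": sorted(t.folded_chains)}
               for sid, t in truths.items()}
    (OUTDIR / "ground_truth.json").write_text(
        json.dumps(sidecar, indent=1, sort_keys=True) + "\n")
    print(f"ground truth: {OUTDIR / 'ground_truth.json'}")


if __name__ == "__main__":
    main()
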