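#!/usr/bin/env python
"""Build the full-size surface semilandmark template.

Samples 100 midfacial, 1000 calvarial and 52 lower-occipital points on
the left side of the reference cranium by farthest-point sampling,
mirrors them across the midsagittal plane and projects the mirrored set
back to the surface: 2304 semilandmarks in total, 200 over the mid-face
and 2104 over the neurocranium.  Writes the point table and a counts
summary under results/template/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from craniogrow.semilandmarks import DEFAULT_PATCH_COUNTS, build_template
from craniogrow.synthetic import default_params, make_template_skull


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--resolution", type=int, default=4)
    ap.add_argument("--out", default="results/template")
    args = ap.parse_args()

    spec = make_template_skull(args.resolution, default_params())
    tpl = build_template(spec.mesh, spec.landmarks,
                         counts=DEFAULT_PATCH_COUNTS, seed=args.seed)
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "x": tpl.slm_points[:, 0], "y": tpl.slm_points[:, 1],
        "z": tpl.slm_points[:, 2], "patch": tpl.patch_tags,
        "side": tpl.side_tags,
    }).to_csv(out / "template_slms.csv", index=False, float_format="%.12g")
    counts = {
        "total": int(tpl.n_slm),
        "midface": int(tpl.module_mask("face").sum()),
        "neurocranium": int(tpl.module_mask("neurocranium").sum()),
        "one_sided": tpl.counts,
    }
    with open(out / "counts.json", "w") as fh:
        json.dump(counts, fh, indent=1)
    print(f"template: {counts['total']} SLMs "
          f"({counts['midface']} mid-facial, "
          f"{counts['neurocranium']} neurocranial) -> {out}")


if __name__ == "__main__":
    main()
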