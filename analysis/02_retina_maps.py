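"""Visualize the retina stage: ON/OFF cortical maps and magnification.

Dumps Fig-style panels (ON and OFF ganglion activity in log-polar cortical
coordinates) for the Vernier display, and tabulates how the cortical
footprint of a fixed-angular-size bar shrinks with eccentricity — the
model's source of inward-outward asymmetry.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from crowdsim import retina as ret
from crowdsim import stimuli as stim

OUT = Path(__file__).resolve().parent.parent / "results"


def bar_scene(ecc, geom):
    img = np.full(geom.shape, stim.BACKGROUND)
    r = geom.fixation[0]
    c = geom.col_of(ecc)
    img[int(r - 12):int(r + 13), int(c - 1):int(c + 2)] = stim.FOREGROUND
    return stim.VisualScene(img, geom.deg_per_pixel, geom.fixation)


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    geom = stim.SceneGeometry()
    params = ret.RetinaParams()

    scene = stim.render_vernier(stim.condition_table("exp1b")[1], geom)
    retinal = ret.retina_pipeline(scene, params)
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
    axes[0].imshow(scene.pixels, cmap="gray")
    axes[0].set_title("scene (inner-flanked Vernier)")
    axes[1].imshow(retinal.on, cmap="magma")
    axes[1].set_title("ON ganglion activity (cortical)")
    axes[2].imshow(retinal.off, cmap="magma")
    axes[2].set_title("OFF ganglion activity (cortical)")
    for ax in axes:
        ax.set_xticks([]), ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(OUT / "retina_maps.png", dpi=120)

    rows = []
    for ecc in (2.0, 4.0, 8.0):
        r = ret.retina_pipeline(bar_scene(ecc, geom), params)
        act = r.on + r.off
        rows.append({"eccentricity_deg": ecc,
                     "halfmax_footprint_px": int((act > act.max() / 2).sum())})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "magnification_footprints.csv", index=False)
    print(df.to_string(index=False))
    print("\nThe same bar occupies fewer cortical pixels at larger "
          "eccentricity: peripheral flankers are represented more coarsely "
          "and closer to the target than foveal ones.")


if __name__ == "__main__":
    main()
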