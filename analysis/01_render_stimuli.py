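"""Render every stimulus condition of both paradigms and the square array.

Writes calibrated grayscale PNGs (with JSON sidecars carrying the angular
calibration and the full condition spec) under results/stimuli/ and prints a
per-condition geometry summary.
"""

from pathlib import Path

import crowdsim
from crowdsim import stimuli as stim

OUT = Path(__file__).resolve().parent.parent / "results" / "stimuli"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    geom = stim.SceneGeometry()
    for eid in ("exp1b", "exp5"):
        for spec in stim.condition_table(eid):
            scene = stim.render_scene(spec, geom)
            scene.save(OUT / f"{spec.label}.png")
            boxes = scene.meta["boxes"]
            print(f"{spec.label:24s} target={boxes['target']}"
                  + (f" flanker={boxes['flanker']}" if "flanker" in boxes
                     else ""))
    for n in (1, 5):
        spec = stim.StimulusSpec("squares_demo", stim.EXP1B_ECCENTRICITY,
                                 n_squares=n)
        scene = stim.render_square_array(n, spec, geom)
        scene.save(OUT / f"squares_{n}.png")
        print(f"squares_{n}: {len(scene.meta['boxes']['squares'])} squares")
    print(f"\nwrote PNGs to {OUT}")


if __name__ == "__main__":
    main()
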