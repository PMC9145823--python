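"""De-skew a tilted recording before analysis.

Renders a particle-free outlet frame at a 3 degree tilt and runs the
iterative rotate-crop-verify loop; the residual skew of the output is
re-measured as the convergence check.
"""

from dldflow.geometry import auto_rotate, estimate_skew_angle
from dldflow.synthetic import VideoFixtureConfig, generate_dld_video

cfg = VideoFixtureConfig(n_particles=0, skew_angle=3.0, n_frames=1, seed=1)
seq, truth = generate_dld_video(cfg)

tilt = estimate_skew_angle(seq[0])
print(f"applied skew     : {truth.applied_skew:+.2f} deg")
print(f"estimated skew   : {tilt:+.2f} deg")

rotated, result = auto_rotate(seq[0], tolerance=0.5, max_iterations=5)
print(f"applied rotation : {result.total_angle:+.2f} deg "
      f"in {result.iterations} iteration(s), converged={result.converged}")
print(f"residual skew    : {estimate_skew_angle(rotated):+.2f} deg")
# residual within the 0.5 degree tolerance means the outlet walls are
# horizontal enough for template matching and wall detection.
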