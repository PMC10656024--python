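"""Calibrate the free parameters against synthetic cordocentesis targets.

Generates gestational-age-indexed fetal subclass means/SDs from a known
ground-truth parameter set, then runs the iterative LHS sample-prune
calibrator and checks that the truth lies inside the accepted ranges —
the parameter-recovery experiment that validates the calibrator.
"""

from placigg import default_parameters, default_ranges
from placigg.calibration import calibrate
from placigg.fixtures import FixtureSpec, generate_cordocentesis_fixture

truth = default_parameters()
targets = generate_cordocentesis_fixture(FixtureSpec(truth=truth, cv=0.25))

result = calibrate(default_ranges(), targets, n_samples=60, seed=3, max_iter=5)
print(f"converged: {result.converged} in {result.iterations} iteration(s)")
print(f"pass fraction per iteration: {[round(f, 3) for f in result.pass_fraction]}")

recovered = 0
for name, (lo, hi) in result.accepted_ranges.bounds.items():
    inside = lo <= getattr(truth, name) <= hi
    recovered += inside
    print(f"  {name:22s} accepted [{lo:.4g}, {hi:.4g}]"
          f"  truth {getattr(truth, name):.4g} {'ok' if inside else 'MISSED'}")
print(f"truth recovered for {recovered}/11 parameters")
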