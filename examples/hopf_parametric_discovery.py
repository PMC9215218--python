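"""Discover a parametric normal form from noisy multi-parameter data.

Eight trajectories of the Hopf normal form (omega = A = 1), one per value
of the bifurcation parameter mu in [-0.2, 0.6], sampled at dt=0.2 and
corrupted with 1% Gaussian sensor noise.  Treating mu as an extra
dictionary variable lets a single sparse fit recover the mu-dependence:
dx/dt = mu x - y - x(x^2+y^2) and its y-counterpart.  A degree-assessment
sweep first confirms that fidelity plateaus at polynomial degree 3.
"""

from rk4sindy import run_hopf_parametric, symbolic_export

report = run_hopf_parametric(seed=0, assess_degrees=[1, 2, 3, 4, 5])

print("dictionary-degree assessment (dense-fit fidelity):")
for row in report.extras["degree_table"]:
    print(f"  degree {row['degree']}: fidelity {row['fidelity']:.3e} "
          f"({row['n_features']} features)")
print(f"selected degree: {report.extras['selected_degree']}")

print("\ndiscovered parametric model:")
print(symbolic_export(report.fitted_model, precision=4))
print(f"\nexact normal-form support: {report.support_match}")
print(f"max relative coefficient error: {report.max_rel_coeff_error_pct:.3f} %")
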