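"""Exact symbolic read-out of a five-layer symbolic network.

Builds the reference network (multiplication units f1, f4, f5 and division
units f2, f3 over the ten-channel demo library), evaluates it numerically at
u = v = 1, and expands it exactly into a closed-form expression with
rational arithmetic.
"""

from fracpde import symnet as sn

params = sn.worked_example_params()

vals = {"u": 1.0, "ux": 0.0, "uxx": 0.0, "v": 1.0, "vx": 0.0, "vxx": 0.0,
        "u2": 1.0, "v2": 1.0, "ualpha": 1.0, "I": 1.0}
out = sn.symnet_forward(params, [vals[c] for c in params.channels])
print(f"network value at u = v = 1 (derivatives zero): {out:.6f}")

model = sn.symnet_to_expression(params, exact=True)
print("\nexact expansion, polynomial part coefficients:")
for mono in ["u_xx", "u", "v", "u**2", "u*v", "v**2"]:
    print(f"  {mono:6s}: {model.coefficient(mono)}")
print("\nrational terms:")
for t in model.terms:
    if t.den is not None:
        print("  ", t)
print(
    "\nThe coefficient of u collects 0.1 from the read-out plus 1 from the"
    "\nexpanded product (u+v+1)(u+v); the division units stay as rational"
    "\nterms with explicit numerator and denominator polynomials."
)
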