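"""Quantize one examination record and score its hypertension risk.

Each raw attribute (category or measurement) is mapped to a small integer
code; the risk value is the dot product of the code vector with
per-attribute importance weights.  Here we use the published reference
weights of the original community study.
"""

from fdacbr import default_scheme, encode_record, risk_value
from fdacbr.weights import load_published_weights

record = {
    "gender": "Male",
    "age": 52.0,                    # 35-65 band -> code 2
    "exercise_frequency": "Occasionally",
    "dietary_habit": "Meat diet",
    "smoking": "Never",
    "drinking": "Occasionally",
    "heart_rhythm": "Normal",
    "central_obesity": "Yes",
    "bmi": 27.2,                    # overweight band -> code 2
    "diabetes": "Yes",
    "heart_rate": 78.0,
    "blood_urea": 6.1,
    "total_cholesterol": 5.6,
    "triglyceride": 2.1,
    "ldl_cholesterol": 3.4,
    "hdl_cholesterol": 1.1,
}

scheme = default_scheme()
codes = encode_record(record, scheme)
weights = load_published_weights()

print("attribute codes (scheme order):")
for name, code in zip(scheme.names, codes):
    print(f"  {name:20s} {int(code)}   (weight {weights[name]:.3f})")

risk = risk_value(codes, weights)
print(f"\nrisk value = sum(code * weight) = {risk:.3f}")
print("A higher risk value means this examination's profile carries more")
print("weighted hypertension risk factors; the time series of these values")
print("over successive exams forms the resident's risk trajectory.")
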