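"""Fixed class ordering shared by every stage.

``HNA`` stands for the hemorrhage/necrotic area class (written "H/NA" in
pathology shorthand; the slash is dropped so labels are filesystem-safe).
"""

# Tumor region, normal liver tissue, portal area, fibrosis,
# hemorrhage/necrotic area, lymphocyte area — this order is the contract
# between classifier outputs, classification maps and signature blocks.
CLASS_LABELS: tuple[str, ...] = ("TR", "NLT", "PA", "FI", "HNA", "LA")

N_CLASSES = len(CLASS_LABELS)

CLASS_TO_CODE = {label: i for i, label in enumerate(CLASS_LABELS)}

# Code used in truth masks / label grids for non-tissue (white background
# or tiles excluded by the coverage rule).
BACKGROUND_CODE = -1
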