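"""Translate a published RMSE into VEcv, and a VEcv into the error measures.

Only the validation set's summary statistics (n, sd, mean) are needed:
the squared-error conversions are exact algebraic identities.
"""

from vecv import ConversionContext, error_to_vecv, vecv_to_error_report

# a study reports RMSE = 1.78 on a validation set with n=30, s=8.80, mean=15.5
ctx = ConversionContext(n=30, s=8.803408, mean_observed=15.5)
v = error_to_vecv("rmse", 1.7753, ctx)
print(f"RMSE 1.7753  ->  VEcv = {v:.2f}%")

# and the reverse: what errors does VEcv = 50% imply on this dataset?
rep = vecv_to_error_report(50.0, ctx)
for key in ("mae", "rmse", "rrmse_pct", "srmse", "msre"):
    print(f"VEcv 50%  ->  {key} = {rep[key]:.4f}  ({rep['exactness'][key]})")

# The MSE-family entries are exact; the MAE/RMAE entries use the empirical
# RMSE/MAE ratio sqrt(2.0572) observed across many validation studies.
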