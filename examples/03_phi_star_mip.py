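"""Integrated information (Phi*) and the minimum information partition.

Builds two 4-channel vector-autoregressive systems - one with cross-group
coupling, one disconnected - and shows that Phi* at the minimum information
partition (MIP) separates them: Phi* vanishes exactly when the dynamics
factorize across the cut.
"""
import numpy as np

from vpckit import find_mip, mutual_information


def var1_covariances(A):
    """Stationary covariance, lag-1 cross-covariance of X_t = A X_{t-1} + e."""
    S = np.eye(A.shape[0])
    for _ in range(2000):
        S = A @ S @ A.T + np.eye(A.shape[0])
    return S, A @ S, S


parts = {"CN": [0], "F_d": [1], "L_s": [2], "L_d": [3]}

coupled = 0.45 * np.eye(4)
coupled[0, 2] = coupled[2, 0] = 0.3     # CN <-> L_s interaction
coupled[1, 3] = 0.2                      # F_d -> L_d drive

disconnected = np.zeros((4, 4))
disconnected[:2, :2] = [[0.5, 0.3], [0.2, 0.4]]   # {CN, F_d} island
disconnected[2:, 2:] = [[0.6, 0.1], [0.3, 0.5]]   # {L_s, L_d} island

for name, A in (("coupled", coupled), ("disconnected", disconnected)):
    cov_t, cov_cross, cov_lag = var1_covariances(A)
    res = find_mip(cov_t, cov_cross, cov_lag, parts)
    i = mutual_information(cov_t, cov_cross, cov_lag)
    print(f"{name} system:")
    print(f"  lagged mutual information I = {i:.4f} nats")
    print(f"  MIP = {res.mip[0]} | {res.mip[1]}  (weakest link of the network)")
    print(f"  Phi* at MIP = {res.phi_star:.6f} nats "
          f"(normalization N_P = {res.normalization:.3f})\n")

print("Phi* = I - I* is the information the system carries about its own "
      "past that no partitioned model can account for; it is ~0 for the "
      "disconnected system and positive when the groups genuinely interact.")
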