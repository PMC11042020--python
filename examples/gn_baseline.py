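"""Gauss-Newton absolute reconstruction of a single-sphere phantom.

Simulates a noiseless frame for a near-insulating sphere, reconstructs the
conductivity with the damped Tikhonov Gauss-Newton solver, and scores the
result with RMSE / CC / SSIM plus the wall-clock solving time (IPST).
"""

from eit3d import (
    AcrylicPhantomSpec,
    CEMParams,
    CylinderSpec,
    FEMContext,
    GNConfig,
    Shape,
    acrylic_field,
    build_cylinder_mesh,
    build_protocol,
    evaluate_reconstruction,
    extract_frame,
    gn_reconstruct,
)

pattern, scheme = build_protocol()
mesh = build_cylinder_mesh(CylinderSpec(), refinement=1)
cem = CEMParams()
ctx = FEMContext(mesh, cem)

truth = acrylic_field(mesh, AcrylicPhantomSpec((Shape("sphere", (1.5, 0.5, 4.0), (1.2,)),)))
frame = extract_frame(ctx.solve(truth, pattern), scheme)

res = gn_reconstruct(frame, mesh, cem, (pattern, scheme), GNConfig(), context=ctx)
rep = evaluate_reconstruction(res.field, truth, ipst_s=res.ipst_s)
print(f"accepted iterations: {res.n_iters}")
print("objective history:", " ".join(f"{o:.3e}" for o in res.objective_history))
print(f"RMSE {rep.rmse:.4e} S/m | CC {rep.cc:.3f} | SSIM {rep.ssim:.3f} | IPST {rep.ipst_s:.2f} s")
print("CC well above 0 means the sphere is localized; the classical solver "
      "saturates around CC ~ 0.7 on this mesh.")
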