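"""Machine-readable manifest of the implemented governing equations.

Each entry names the parameter-registry fields and the dynamic state fields
the equation consumes, so a coverage test can verify that every symbol
resolves to exactly one registry or state field.
"""

from __future__ import annotations

EQUATIONS: dict[str, dict[str, list[str]]] = {
    "release_L": {
        "params": ["K_L", "n_L"],
        "states": ["m_CL", "h_CL", "C_L", "C_m"],
    },
    "release_membrane": {"params": ["K_m", "n_m"], "states": ["C_m"]},
    "release_N": {
        "params": ["K_N", "n_N"],
        "states": ["m_CN", "h_CN", "C_N", "C_m"],
    },
    "microdomain_L": {
        "params": ["f", "alpha", "lambda_ud", "B_ud", "g_CL", "N_L", "V_C"],
        "states": ["C_L", "C_m", "v_m"],
    },
    "microdomain_N": {
        "params": ["f", "alpha", "lambda_ud", "B_ud", "g_CN", "N_N", "V_C"],
        "states": ["C_N", "C_m", "v_m"],
    },
    "submembrane": {
        "params": [
            "f", "lambda_m", "alpha", "g_CT", "V_C", "N_L", "lambda_ud", "B_ud",
            "lambda_c", "k_PMCA", "B_m",
        ],
        "states": ["C_m", "C_L", "C_c", "m_CT", "h_CTf", "h_CTs", "m_CL", "h_CL", "v_m"],
    },
    "cytosol_neuron": {
        "params": ["f", "B_m", "p_leak", "k_SERCA"],
        "states": ["C_c", "C_m", "C_r"],
    },
    "er_neuron": {
        "params": ["f", "lambda_c", "lambda_r", "p_leak", "k_SERCA"],
        "states": ["C_r", "C_c"],
    },
    "hh_gates": {
        "params": [],
        "states": ["v_m", "m_Na", "h_Na", "m_K"],
    },
    "membrane_neuron": {
        "params": ["c_m", "g_K_bar", "g_Na_bar", "g_L", "V_K", "V_Na", "V_L"],
        "states": ["v_m", "m_K", "m_Na", "h_Na"],
    },
    "ip3_production": {"params": ["IP3_0", "tau_P", "r_P"], "states": ["P"]},
    "cytosol_astrocyte": {
        "params": ["c0", "c1", "v1", "v2", "v3", "k3", "n4", "d1", "d5", "d6"],
        "states": ["C_c", "P", "h_P"],
    },
    "ip3r_inactivation": {
        "params": ["a2_ip3r", "d1", "d2", "d3"],
        "states": ["h_P", "P", "C_c"],
    },
    "vgcc_total_current": {
        "params": ["g_T_bar", "g_L_bar", "g_N_bar", "g_R_bar", "V_C", "A_VL"],
        "states": ["v_m", "m_T", "h_Tf", "h_Ts", "m_L", "m_N", "m_R", "h_R", "C_c"],
    },
    "vgcc_flux": {"params": ["z_Ca", "F", "lambda_ast"], "states": ["v_m"]},
    "flux_cicr": {
        "params": ["M_CICR", "P_CA", "P_CI", "P_IP3", "n1", "n2"],
        "states": ["C_c", "C_r", "P_c"],
    },
    "flux_serca": {"params": ["M_SERCA", "P_SERCA", "n4"], "states": ["C_c"]},
    "flux_ryr": {"params": ["k1", "k2", "k_d", "A_RyR", "n3"], "states": ["C_c", "C_r"]},
    "flux_er_leak": {"params": ["P_f"], "states": ["C_r", "C_c"]},
    "flux_in": {"params": ["a1", "a2_in", "A_in", "n5"], "states": ["P_c"]},
    "flux_pm": {"params": ["lambda_PM", "K_pm", "n4"], "states": ["C_c"]},
    "flux_plc": {"params": ["A_m", "M_PLC", "P_PC", "n4"], "states": ["C_c"]},
    "ip3_abeta": {"params": ["P_deg"], "states": ["P_c"]},
    "feedback_current": {"params": ["A_astro"], "states": ["C_c"]},
    "trpm8_gate": {"params": ["dH", "dS", "z_gate", "F", "R_gas"], "states": ["v_m"]},
    "trpm8_current": {"params": ["g_m8", "V_m8"], "states": ["v_m"]},
    "phi_factors": {
        "params": [
            "phi_mK_pref", "phi_mK_q10", "phi_mNa_pref", "phi_mNa_q10",
            "phi_hNa_pref", "phi_hNa_q10",
        ],
        "states": [],
    },
    "peak_conductances": {
        "params": [
            "gK_max_amp", "gK_max_T0", "gK_max_sigma",
            "gNa_max_amp", "gNa_max_T0", "gNa_max_sigma",
        ],
        "states": [],
    },
}

#: every state field name used across the model variants
STATE_FIELDS = {
    "v_m", "m_Na", "h_Na", "m_K", "m_CL", "h_CL", "m_CT", "h_CTf", "h_CTs",
    "C_L", "C_m", "C_c", "C_r", "P", "h_P", "m_CN", "h_CN", "C_N",
    "P_c", "m_T", "h_Tf", "h_Ts", "m_L", "m_N", "m_R", "h_R",
}
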