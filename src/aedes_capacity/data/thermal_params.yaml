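# Default enzyme-kinetics (Sharpe-Schoolfield) parameters for the three
# temperature-dependent development rates of Aedes aegypti, after Focks et al.
#
# Units:
#   rho : development rate (per day) at the 298 K reference temperature,
#         assuming no high-temperature enzyme inactivation
#   a   : Arrhenius activation enthalpy (cal/mol)
#   b   : high-temperature inactivation enthalpy (cal/mol)
#   tau : temperature (Kelvin) at which half the rate-controlling enzyme
#         is inactivated (often written T_1/2H)
#
# schema_version bumps if the layout changes; values are literature constants.
schema_version: 1
egg_eclosion:
  rho: 0.24
  a: 10798.0
  b: 100000.0
  tau: 14184.0
pupation:
  rho: 0.2088
  a: 26018.0
  b: 55990.0
  tau: 304.6
emergence:
  rho: 0.384
  a: 14931.0
  b: -472379.0
  tau: 148.0
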