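regimen_label,parameter,day,predicted,observed,printed_error_pct,units
"600 mg IV, SD",Cmax,,31.9,37.6,-15.16,ug/mL
"600 mg IV, SD",Tmax,,1,1.06,-5.66,h
"600 mg IV, SD",AUC,,93.73,114,-17.78,ug*h/mL
"600 mg IV, SD",V,,18.28,13.67,33.72,L
"600 mg IV, SD",CL,,6.24,5.15,21.17,L/h
"600 mg IV, SD",T1/2,,2.22,2.21,0.45,h
"200 mg oral, SD",Cmax,,8.92,10.3,15.59,ug/mL
"200 mg oral, SD",Tmax,,1.98,1.7,-14.57,h
"200 mg oral, SD",AUC,,49.6,60,20.94,ug*h/mL
"200 mg oral, SD",V/F,,44.24,50.88,-13.05,L
"200 mg oral, SD",CL/F,,7.9,10.49,-24.69,L/h
"200 mg oral, SD",T1/2,,3.63,2.74,32.32,h
"400 mg oral, SD",Cmax,,11.53,8.71,-24.5,ug/mL
"400 mg oral, SD",Tmax,,1.92,1.85,-3.77,h
"400 mg oral, SD",AUC,,59.41,41.56,-30.05,ug*h/mL
"400 mg oral, SD",V/F,,46.03,42.12,9.29,L
"400 mg oral, SD",CL/F,,8.94,7.81,14.54,L/h
"400 mg oral, SD",T1/2,,3.37,2.95,14.24,h
"600 mg oral, QD-1",Cmax,1,14.2,13,9.23,ug/mL
"600 mg oral, QD-1",AUC,1,70.34,85.63,-17.86,ug*h/mL
"600 mg oral, QD-1",V/F,1,35.27,61.44,-42.59,L
"600 mg oral, QD-1",CL/F,1,8.52,6.23,36.76,L/h
"600 mg oral, QD-1",T1/2,1,2.54,11.54,-77.99,h
"600 mg oral, QD-1",Cmax,4,11.3,11.3,0,ug/mL
"600 mg oral, QD-1",AUC,4,43.74,48.43,-9.68,ug*h/mL
"600 mg oral, QD-1",V/F,4,44.76,50.74,-11.79,L
"600 mg oral, QD-1",CL/F,4,12.74,9.86,29.21,L/h
"600 mg oral, QD-1",T1/2,4,2.06,3.43,-39.94,h
"600 mg oral, QD-1",Cmax,6,11.2,10.2,9.8,ug/mL
"600 mg oral, QD-1",AUC,6,41.24,34.05,21.12,ug*h/mL
"600 mg oral, QD-1",V/F,6,44.24,54.92,-19.45,L
"600 mg oral, QD-1",CL/F,6,12.96,15.98,-18.9,L/h
"600 mg oral, QD-1",T1/2,6,1.92,1.4,37.14,h
"600 mg oral, QD-2",Cmax,1,20.3,22,-7.73,ug/mL
"600 mg oral, QD-2",AUC,1,89.34,132.27,-32.46,ug*h/mL
"600 mg oral, QD-2",V/F,1,23.9,21.98,56.53,L
"600 mg oral, QD-2",CL/F,1,6.59,4.21,-22.9,L/h
"600 mg oral, QD-2",T1/2,1,2.02,2.62,-4.11,h
"600 mg oral, QD-2",Cmax,4,15.9,13,22.31,ug/mL
"600 mg oral, QD-2",AUC,4,57.55,86.76,-33.67,ug*h/mL
"600 mg oral, QD-2",V/F,4,32.47,33.86,56.4,L
"600 mg oral, QD-2",CL/F,4,10.26,6.56,5.24,L/h
"600 mg oral, QD-2",T1/2,4,2.21,2.1,56.53,h
"600 mg oral, QD-2",Cmax,7,15.8,17.7,-10.73,ug/mL
"600 mg oral, QD-2",AUC,7,57,96.73,-41.07,ug*h/mL
"600 mg oral, QD-2",V/F,7,32.48,25.26,28.58,L
"600 mg oral, QD-2",CL/F,7,10.36,6.11,69.56,L/h
"600 mg oral, QD-2",T1/2,7,2.2,1.46,50.68,h
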