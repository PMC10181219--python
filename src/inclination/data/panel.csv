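name,unit,min,low,normality,high,max,direction
BMI,kg/m^2,10,15,25,35,60,decrease_good
dBP,mmHg,20,60,80,100,192,decrease_good
sBP,mmHg,50,70,120,160,266,decrease_good
fasting_glucose,mmol/L,1.3,3.2,5.6,9,23,decrease_good
HbA1c,%,0.05,3.3,5.7,8,18.5,decrease_good
HDL,mmol/L,0.6,1,1.5,2,3,increase_good
LDL,mmol/L,0.7,1.5,3.4,5.2,8,decrease_good
total_cholesterol,mmol/L,2,4.2,5.2,6.2,13,decrease_good
triglycerides,mmol/L,0.1,0.5,1.7,3.5,20,decrease_good
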