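{"lmm":{"coef":[0.51748972993,-0.26230017299,-0.032467904937,0.014345380223],"se":[0.052418216703,0.035182499645,0.041532773116,0.01977262021],"df":[17.6583119056,18.3990089738,10.0146445612,39.9129835152],"t":[9.8723261203,-7.4554160631,-0.78174180294,0.72551741097],"p":[1.3055814584e-08,5.7459864963e-07,0.45245202292,0.47236743732],"terms":["(Intercept)","consistency","literacy","consistency:literacy"],"varcorr":[{"grp":"item","var1":"(Intercept)","vcov":0.018956370234,"sdcor":0.13768213477},{"grp":"participant","var1":"(Intercept)","vcov":0.016370851461,"sdcor":0.12794862821},{"grp":"participant","var1":"consistency","vcov":0.00044659299139,"sdcor":0.021132746896},{"grp":"participant","var1":"(Intercept)","var2":"consistency","vcov":-0.0027039057699,"sdcor":-0.99999992386},{"grp":"Residual","vcov":0.10059060501,"sdcor":0.31716021978}],"REMLcrit":186.130023676},"glmm":{"coef":[-0.4744136688,-0.77234431522,-0.16460411371,-0.20066348394,-0.010087308907,-0.2456662951,-0.032411305957],"se":[0.23423474784,0.10499208652,0.098394864205,0.30270245955,0.073504901205,0.14778888768,0.11083257315],"z":[-2.0253769912,-7.3562145566,-1.672893347,-0.66290668479,-0.13723314693,-1.662278531,-0.29243484146],"terms":["(Intercept)","session_c","consistency","literacy","session_c:consistency","session_c:literacy","consistency:literacy"],"varcorr":[{"grp":"item","var1":"(Intercept)","vcov":0.075442360276,"sdcor":0.27466772704},{"grp":"participant","var1":"(Intercept)","vcov":0.35625300263,"sdcor":0.59686933464}],"logLik":-277.8208690334},"distance":{"coef":[0.54992931694,-0.019440682202],"se":[0.025271566154,0.0045934602425],"df":[19.7679410527,9.8637602357],"terms":["(Intercept)","session_z"],"REMLcrit":-1026.5666704535}}
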