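land_use,description,total_pahs,bapeq,sampling_depth,contamination_label,reference
urban,Surface soil in urban parks in Beijing,460.0,50.7,0-10,weakly_contaminated,ref021
urban,Urban soils in Beijing,1228.0,159.2,0-10,heavily_contaminated,ref025
urban,"Surface soils in Nankai University, Tianjin",360.0,36.9,0-20,weakly_contaminated,ref029
urban,Surface soils in Beijing,1082.6,180.7,0-20,heavily_contaminated,ref016
urban,Surface soil in schools in Beijing,1989.0,286.6,0-10,heavily_contaminated,ref030
urban,Surface soil in parks in Beijing,1285.0,170.6,0-10,heavily_contaminated,ref030
urban,Surface soil in roadside with heavy traffic in Beijing,1026.0,135.0,0-10,heavily_contaminated,ref030
urban,Surface soil in residential area in Beijing,811.0,98.7,0-10,contaminated,ref030
urban,Surface soil in plantation area in Beijing,673.0,85.3,0-10,contaminated,ref030
urban,Surface soil in roadside with light traffic in Beijing,538.0,68.9,0-10,weakly_contaminated,ref030
urban,Surface soil in vacant area in Beijing,523.0,65.4,0-10,weakly_contaminated,ref030
suburban,"Surface soils in Xiqing, Tianjin",1490.0,178.7,0-20,heavily_contaminated,ref029
suburban,"Surface soils in Jinnan, Tianjin",708.0,85.4,0-20,contaminated,ref029
suburban,"Surface soils in Beicheng, Tianjin",904.0,69.6,0-20,contaminated,ref029
suburban,"Surface soils in Dongli, Tianjin",699.0,48.8,0-20,contaminated,ref029
suburban,"Surface soils in Jinghai, Tianjin",142.0,12.9,0-20,not_contaminated,ref029
suburban,"Surface soils in Jixian, Tianjin",382.0,32.7,0-20,weakly_contaminated,ref029
suburban,"Surface soils in Xiqing, Tianjing",422.8,57.1,0-20,weakly_contaminated,ref031
suburban,Surface soils from Tianjin coastal new region,932.0,124.2,0-10,contaminated,ref022
suburban,"Surface soil in Tongzhou District, Beijing",1004.1,158.4,0-20,heavily_contaminated,ref032
suburban,Surface soils in suburban area of Beijing,321.8,38.1,--,weakly_contaminated,ref023
suburban,Surface soils in suburban area of Beijing and Tianjin,622.4,54.6,0-5,contaminated,ref014
rural,Agricultural soil in suburb of Beijing,460.8,24.8,0-20,weakly_contaminated,ref033
rural,Surface soils in rural area of Beijing,219.2,27.3,--,weakly_contaminated,ref023
rural,Surface soils in rural area of Beijing and Tianjin,195.3,14.8,0-5,not_contaminated,ref014
rural,Arable soils of Beijing,489.6,71.0,0-10,weakly_contaminated,ref019
rural,Agricultural soil in Tianjin,1295.8,185.6,0-5,heavily_contaminated,ref012
rural,Surface soil from garden in Tianjin,1258.6,126.8,0-20,heavily_contaminated,ref013
rural,Surface soil from cropland in Tianjin,624.7,114.4,0-20,contaminated,ref013
rural,Surface soil from dryland in Tianjin,1003.9,97.1,0-20,heavily_contaminated,ref013
rural,Surface soil in residential areas of Tianjin,481.8,4.5,0-20,weakly_contaminated,ref034
rural,Surface soil in residential areas of Tianjin,435.1,10.8,0-20,weakly_contaminated,ref034
rural,Surface soil in residential areas of Tianjin,289.1,3.7,0-20,weakly_contaminated,ref034
rural,Surface soil in agricultural facility areas of Tianjin,175.7,6.9,0-20,not_contaminated,ref034
rural,Surface soil in agricultural facility areas of Tianjin,296.1,25.5,0-20,weakly_contaminated,ref034
rural,Surface soil in agricultural facility areas of Tianjin,229.3,11.9,0-20,weakly_contaminated,ref034
rural,Surface soil in agricultural facility areas of Tianjin,286.0,17.0,0-20,weakly_contaminated,ref034
rural,Surface soil in farmland around livestock breeding areas of Tianjin,772.9,10.9,0-20,contaminated,ref034
rural,Surface soil in farmland around livestock breeding areas of Tianjin,259.9,4.1,0-20,weakly_contaminated,ref034
rural,Surface soil in farmland around industrial areas of Tianjin,323.3,55.2,0-20,weakly_contaminated,ref034
rural,Vegetable soils from the Beijing-Tianjin,602.5,111.4,0-20,contaminated,ref024
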